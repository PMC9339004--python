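"""Descriptive neural summaries: PSTHs by accumulated-evidence quantile,
rate-versus-evidence fits, and latency-distribution comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .task import (
    DerivedStimulusVars,
    TaskConfig,
    Trial,
    accumulated_evidence,
)

__all__ = [
    "PsthSummary",
    "RateEvidenceFit",
    "psth_by_quintile",
    "rate_vs_evidence_fit",
    "latency_compare",
    "plot_population_kernel",
]


@dataclass
class PsthSummary:
    """Trial-averaged rates aligned to one epoch's stimulus onset, grouped by
    choice and accumulated-evidence quantile."""

    epoch: int
    time_ms: np.ndarray                      # relative to the stimulus onset
    rates: Dict[Tuple[str, int], np.ndarray]  # (choice, quantile) -> mean rate
    sems: Dict[Tuple[str, int], np.ndarray]
    group_sizes: Dict[Tuple[str, int], int]
    n_quantiles: int


@dataclass
class RateEvidenceFit:
    """OLS fit of binned mean firing rate against accumulated evidence."""

    epoch: int
    choice: str
    bin_evidence: np.ndarray   # six bin means of accumulated evidence
    bin_rate: np.ndarray       # six bin means of firing rate (sp/s)
    slope: float
    intercept: float
    p_value: float             # two-tailed, on the slope, unadjusted
    slope_se: float


def _population_rate_per_trial(
    counts_by_neuron: Sequence[Sequence[np.ndarray]],
) -> List[np.ndarray]:
    """Mean rate across neurons, per trial, in counts-per-bin units."""
    n_trials = len(counts_by_neuron[0])
    out = []
    for t in range(n_trials):
        out.append(
            np.mean([np.asarray(c[t], dtype=float) for c in counts_by_neuron], axis=0)
        )
    return out


def _quantile_groups(values: np.ndarray, n_groups: int) -> List[np.ndarray]:
    """Equal-count groups by sorted value; sizes differ by at most one.
    Ties are broken by original order (stable sort)."""
    order = np.argsort(values, kind="stable")
    return np.array_split(order, n_groups)


def psth_by_quintile(
    counts_by_neuron: Sequence[Sequence[np.ndarray]],
    trials: Sequence[Trial],
    derived_vars: Sequence[DerivedStimulusVars],
    epoch: int,
    task_config: Optional[TaskConfig] = None,
    window_ms: Tuple[int, int] = (-100, 1000),
    smoothing_ms: int = 0,
    n_quantiles: int = 5,
    bin_ms: int = 10,
) -> PsthSummary:
    """Population PSTH aligned to one epoch's stimulus onset.

    Trials are split by choice (T_in / T_out) and, within choice, into
    ``n_quantiles`` equal-count groups of accumulated evidence through that
    epoch. Rates are averaged across trials then across neurons; the s.e. is
    across neurons. ``smoothing_ms`` applies a causal boxcar.
    """
    task_config = task_config or TaskConfig()
    onset_bin = task_config.stim_onset_ms(epoch) // bin_ms
    lo = onset_bin + window_ms[0] // bin_ms
    hi = onset_bin + window_ms[1] // bin_ms
    time_ms = (np.arange(lo, hi) - onset_bin) * bin_ms

    acc = np.array([accumulated_evidence(d, epoch) for d in derived_vars])
    choice = np.array([t.choice for t in trials])
    if any(c is None for c in choice):
        raise ValueError("all trials need a choice")

    # per-neuron, per-trial aligned window with NaN padding past the go cue
    n_neurons = len(counts_by_neuron)
    n_trials = len(trials)
    width = hi - lo
    aligned = np.full((n_neurons, n_trials, width), np.nan)
    for ni, per_trial in enumerate(counts_by_neuron):
        for ti, c in enumerate(per_trial):
            c = np.asarray(c, dtype=float)
            a, b = max(lo, 0), min(hi, len(c))
            aligned[ni, ti, a - lo : b - lo] = c[a:b]
    aligned /= bin_ms / 1000.0  # counts/bin -> spikes/s

    rates, sems, sizes = {}, {}, {}
    for ch in ("T_in", "T_out"):
        idx = np.where(choice == ch)[0]
        if len(idx) == 0:
            warnings.warn(f"no trials with choice {ch}; group dropped")
            continue
        for qi, grp in enumerate(_quantile_groups(acc[idx], n_quantiles)):
            sel = idx[grp]
            if len(sel) == 0:
                warnings.warn(f"empty quantile {qi} for choice {ch}; dropped")
                continue
            per_neuron = np.nanmean(aligned[:, sel, :], axis=1)  # (neurons, time)
            trace = per_neuron.mean(axis=0)
            sem = (
                per_neuron.std(axis=0, ddof=1) / np.sqrt(n_neurons)
                if n_neurons > 1
                else np.full(width, np.nan)
            )
            if smoothing_ms > 0:
                w = max(1, smoothing_ms // bin_ms)
                kern = np.ones(w) / w
                # causal: each bin averages the preceding w bins
                trace = np.convolve(trace, kern)[: len(trace)]
                sem = np.convolve(sem, kern)[: len(sem)]
            rates[(ch, qi)] = trace
            sems[(ch, qi)] = sem
            sizes[(ch, qi)] = len(sel)
    return PsthSummary(
        epoch=epoch,
        time_ms=time_ms,
        rates=rates,
        sems=sems,
        group_sizes=sizes,
        n_quantiles=n_quantiles,
    )


def rate_vs_evidence_fit(
    counts_by_neuron: Sequence[Sequence[np.ndarray]],
    trials: Sequence[Trial],
    derived_vars: Sequence[DerivedStimulusVars],
    epoch: int,
    task_config: Optional[TaskConfig] = None,
    rate_window_ms: Tuple[int, int] = (300, 800),
    n_bins: int = 6,
    bin_ms: int = 10,
) -> Dict[str, RateEvidenceFit]:
    """Mean rate 300-800 ms after the epoch's stimulus onset, binned into six
    equal-count groups of accumulated evidence, fitted by OLS per choice.

    The window is used literally even where it spans into the next epoch.
    Returns one fit per choice group.
    """
    task_config = task_config or TaskConfig()
    onset_bin = task_config.stim_onset_ms(epoch) // bin_ms
    a = onset_bin + rate_window_ms[0] // bin_ms
    b = onset_bin + rate_window_ms[1] // bin_ms
    pop = _population_rate_per_trial(counts_by_neuron)
    rate = np.array(
        [np.mean(r[a : min(b, len(r))]) / (bin_ms / 1000.0) for r in pop]
    )
    acc = np.array([accumulated_evidence(d, epoch) for d in derived_vars])
    choice = np.array([t.choice for t in trials])

    out = {}
    for ch in ("T_in", "T_out"):
        idx = np.where(choice == ch)[0]
        if len(idx) < n_bins:
            raise ValueError(
                f"choice group {ch} has {len(idx)} trials; need >= {n_bins}"
            )
        groups = _quantile_groups(acc[idx], n_bins)
        ev = np.array([acc[idx][g].mean() for g in groups])
        fr = np.array([rate[idx][g].mean() for g in groups])
        res = stats.linregress(ev, fr)
        out[ch] = RateEvidenceFit(
            epoch=epoch,
            choice=ch,
            bin_evidence=ev,
            bin_rate=fr,
            slope=float(res.slope),
            intercept=float(res.intercept),
            p_value=float(res.pvalue),
            slope_se=float(res.stderr),
        )
    return out


def plot_population_kernel(kernels, bin_ms: int = 10, ax=None, label=None,
                           sig_trace=None):
    """Minimal helper: population mean kernel with an s.e. band and an
    optional significance bar along the abscissa."""
    import matplotlib.pyplot as plt

    K = np.atleast_2d(np.asarray(kernels, dtype=float))
    t = np.arange(K.shape[1]) * bin_ms
    mean = K.mean(axis=0)
    se = K.std(axis=0, ddof=1) / np.sqrt(K.shape[0]) if K.shape[0] > 1 else 0 * mean
    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.fill_between(t, mean - se, mean + se, alpha=0.3)
    ax.plot(t, mean, label=label)
    if sig_trace is not None:
        y0 = (mean - se).min()
        ax.plot(t[np.asarray(sig_trace, bool)],
                np.full(int(np.sum(sig_trace)), y0), "s", ms=2, color="k")
    ax.set_xlabel("time from event onset (ms)")
    ax.set_ylabel("kernel weight (log rate)")
    return ax


def latency_compare(latencies_a: Sequence[float], latencies_b: Sequence[float]) -> Tuple[float, float]:
    """Classic two-sample t test (pooled variance, two-tailed) on encoding
    latencies from two neuron groups."""
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each latency set needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            raise ValueError("both sets constant and identical: t undefined")
        raise ValueError("zero variance in both sets: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
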