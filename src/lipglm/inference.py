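"""Statistical inference on fitted response kernels.

Significance is permutation-based: a variable's per-trial values are
shuffled across trials (event times kept), the full GLM is refit, and the
shuffled-fit kernels form the null. Per lag, the observed kernel weight is
compared to the null with a two-tailed t statistic (p < 0.01); a neuron
counts as encoding the variable only when its longest run of significant
lags exceeds the 95th percentile of the null's own longest-run
distribution. Latency is the start of the first significant run and the
encoding sign is the sign of the mean kernel weight over that run.

Also here: the coefficient of partial determination (CPD) with shuffled-
variable refits, population-level kernel t tests, selectivity
classification for the sw_in/sw_out split model, and reduced-major-axis
(model II) regression with permutation significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import glm

__all__ = [
    "NullKernelSet",
    "EncodingResult",
    "Model2Fit",
    "shuffle_null_kernels",
    "per_bin_significance",
    "longest_run",
    "significant_runs",
    "neuron_significance",
    "cpd",
    "cpd_value",
    "population_kernel_test",
    "swin_swout_classify",
    "model2_regression",
]

logger = logging.getLogger(__name__)

ALPHA = 0.01  # per-lag two-tailed level used throughout


@dataclass
class NullKernelSet:
    """Kernels refit under trial-shuffles of one variable."""

    variable: str
    kernels: np.ndarray          # (n_shuffles, n_lags)
    seed: int
    n_failed: int = 0

    def __post_init__(self):
        self.kernels = np.atleast_2d(np.asarray(self.kernels, dtype=float))
        if self.kernels.shape[0] < 2:
            raise ValueError("need at least 2 shuffles")

    @property
    def n_shuffles(self) -> int:
        return self.kernels.shape[0]


@dataclass
class EncodingResult:
    """Per neuron x variable: the full shuffle-test outcome."""

    variable: str
    p_values: np.ndarray
    sig_trace: np.ndarray
    longest_run_ms: float
    null_threshold_ms: float
    significant: bool
    latency_ms: Optional[float]
    sign: str                    # "positive" | "negative" | "none"
    cpd: Optional[float] = None


def shuffle_null_kernels(
    counts: Sequence[np.ndarray],
    rs: glm.RegressorSet,
    variable: str,
    n_shuffles: int = 100,
    seed: int = 0,
    fit_config: Optional[glm.FitConfig] = None,
    observed_model: Optional[glm.KernelModel] = None,
) -> NullKernelSet:
    """Refit the GLM ``n_shuffles`` times with ``variable`` permuted across
    trials, keeping event times; returns the shuffled kernels.

    Warm-starts each refit from the observed fit (the NLL is convex, so this
    changes nothing but the iteration count). Individual fit failures are
    recorded; more than 10% failing is an error.
    """
    if variable not in rs.variables:
        raise KeyError(f"{variable!r} is not in this regressor set")
    if observed_model is None:
        observed_model = glm.fit_kernels(counts, rs, fit_config)
    rng = np.random.default_rng(seed)
    lags = rs.kernel_lags(variable)
    kernels = np.empty((n_shuffles, lags))
    n_failed = 0
    for s in range(n_shuffles):
        perm = rng.permutation(rs.n_trials)
        overrides = rs.permuted_values(variable, perm)
        try:
            m = glm.fit_kernels(
                counts, rs, fit_config, init=observed_model, overrides=overrides
            )
            kernels[s] = m.kernels[variable]
        except Exception as exc:  # noqa: BLE001 - recorded, rethrown if frequent
            logger.warning("shuffle %d failed: %s", s, exc)
            kernels[s] = np.nan
            n_failed += 1
    if n_failed > 0.1 * n_shuffles:
        raise RuntimeError(
            f"{n_failed}/{n_shuffles} shuffle refits failed for {variable!r}"
        )
    if n_failed:
        keep = ~np.isnan(kernels).any(axis=1)
        kernels = kernels[keep]
    return NullKernelSet(variable=variable, kernels=kernels, seed=seed, n_failed=n_failed)


def _t_trace(observed: np.ndarray, null_kernels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-lag t statistic of an observed kernel against a null sample and
    the two-tailed p values (df = n_null - 1). Zero-variance lags are
    non-testable (p = nan)."""
    n = null_kernels.shape[0]
    mean = null_kernels.mean(axis=0)
    sd = null_kernels.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (observed - mean) / sd
    p = np.full_like(t, np.nan)
    # a numerically constant null (sd at rounding level) is non-testable
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return t, p


def per_bin_significance(
    observed_kernel: np.ndarray,
    null_set: NullKernelSet,
    alpha: float = ALPHA,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean significance trace and per-lag p values for one kernel."""
    if null_set.n_shuffles < 20:
        warnings.warn("fewer than 20 shuffles: per-lag variance is unstable")
    observed = np.asarray(observed_kernel, dtype=float)
    if observed.shape[0] != null_set.kernels.shape[1]:
        raise ValueError("kernel/null lag mismatch")
    _, p = _t_trace(observed, null_set.kernels)
    n_dead = int(np.isnan(p).sum())
    if n_dead:
        logger.info("%d lags non-testable (zero null variance)", n_dead)
    sig = np.zeros(len(p), dtype=bool)
    ok = ~np.isnan(p)
    sig[ok] = p[ok] < alpha
    return sig, p


def significant_runs(trace: np.ndarray) -> List[Tuple[int, int]]:
    """(start_lag, length) of each maximal run of True."""
    trace = np.asarray(trace, dtype=bool)
    if trace.size == 0:
        raise ValueError("empty trace")
    padded = np.concatenate(([False], trace, [False])).astype(int)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def longest_run(trace: np.ndarray, bin_ms: int = 10) -> float:
    """Duration (ms) of the longest consecutive significant stretch."""
    runs = significant_runs(trace)
    return max((length for _, length in runs), default=0) * bin_ms


def neuron_significance(
    observed_kernel: np.ndarray,
    null_set: NullKernelSet,
    alpha: float = ALPHA,
    bin_ms: int = 10,
) -> EncodingResult:
    """Longest-run permutation gate plus latency and sign.

    The null longest-run distribution is built leave-one-out: each shuffled
    kernel is tested against the remaining shuffles and its longest
    significant run recorded; the gate is the 95th percentile of those runs.
    Latency is the beginning of the first run whose duration itself exceeds
    that threshold — an encoding duration that is significant, not merely a
    stretch of per-lag hits (isolated false-positive lags would otherwise
    capture the latency) — and the sign is the sign of the mean observed
    kernel weight over that run.
    """
    observed = np.asarray(observed_kernel, dtype=float)
    sig, p = per_bin_significance(observed, null_set, alpha)
    obs_longest = longest_run(sig, bin_ms)

    null_runs = np.empty(null_set.n_shuffles)
    for s in range(null_set.n_shuffles):
        others = np.delete(null_set.kernels, s, axis=0)
        _, p_s = _t_trace(null_set.kernels[s], others)
        sig_s = np.zeros(len(p_s), dtype=bool)
        ok = ~np.isnan(p_s)
        sig_s[ok] = p_s[ok] < alpha
        null_runs[s] = longest_run(sig_s, bin_ms)
    threshold = float(np.percentile(null_runs, 95))

    significant = obs_longest > threshold
    latency = None
    sign = "none"
    if significant:
        first_start, first_len = next(
            (s, l) for s, l in significant_runs(sig) if l * bin_ms > threshold
        )
        latency = first_start * bin_ms
        mean_w = observed[first_start : first_start + first_len].mean()
        sign = "positive" if mean_w > 0 else "negative"
    return EncodingResult(
        variable=null_set.variable,
        p_values=p,
        sig_trace=sig,
        longest_run_ms=obs_longest,
        null_threshold_ms=threshold,
        significant=bool(significant),
        latency_ms=latency,
        sign=sign,
    )


def cpd_value(sse_reduced: float, sse_full: float) -> float:
    """CPD = (SSE_reduced - SSE_full) / SSE_reduced."""
    if sse_reduced == 0:
        raise ZeroDivisionError("SSE of the reduced model is zero; CPD undefined")
    return (sse_reduced - sse_full) / sse_reduced


def _sse(counts_flat: np.ndarray, model: glm.KernelModel, rs: glm.RegressorSet,
         overrides=None) -> float:
    eta = rs.matrix(overrides) @ model.coef_vector(rs)
    mu = rs.delta_s * np.exp(eta)
    return float(np.sum((counts_flat - mu) ** 2))


def cpd(
    counts: Sequence[np.ndarray],
    rs: glm.RegressorSet,
    variable: str,
    fitted_full_model: glm.KernelModel,
    n_rep: int = 100,
    seed: int = 0,
    fit_config: Optional[glm.FitConfig] = None,
) -> float:
    """Coefficient of partial determination of one variable.

    Per repetition the variable is shuffled across trials, the model refit,
    and the reduced-model SSE compared to the full-model SSE; the returned
    CPD is the mean over repetitions.
    """
    if variable not in rs.variables:
        raise KeyError(f"{variable!r} is not in this regressor set")
    y = rs.flatten_counts(counts)
    sse_full = _sse(y, fitted_full_model, rs)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_rep)
    for r in range(n_rep):
        perm = rng.permutation(rs.n_trials)
        overrides = rs.permuted_values(variable, perm)
        m = glm.fit_kernels(counts, rs, fit_config, init=fitted_full_model,
                            overrides=overrides)
        sse_red = _sse(y, m, rs, overrides)
        vals[r] = cpd_value(sse_red, sse_full)
    return float(vals.mean())


def population_kernel_test(
    kernels: np.ndarray, alpha: float = ALPHA
) -> Dict[str, np.ndarray]:
    """Per-lag one-sample t test of neuron kernels against zero (uncorrected).

    ``kernels`` is (n_neurons, n_lags); returns mean, s.e., t, p, and the
    significance trace at ``alpha``.
    """
    K = np.atleast_2d(np.asarray(kernels, dtype=float))
    if K.shape[0] < 2:
        raise ValueError("need kernels from at least 2 neurons")
    t, p = stats.ttest_1samp(K, 0.0, axis=0)
    return {
        "mean": K.mean(axis=0),
        "se": K.std(axis=0, ddof=1) / np.sqrt(K.shape[0]),
        "t": t,
        "p": p,
        "significant": p < alpha,
    }


def swin_swout_classify(
    kernel_in: np.ndarray,
    kernel_out: np.ndarray,
    null_in: NullKernelSet,
    null_out: NullKernelSet,
    window: Tuple[int, int],
    alpha: float = ALPHA,
) -> dict:
    """Classify a neuron's selectivity for the routed weights.

    Selectivity is the mean kernel weight over ``window`` (lag indices,
    half-open). Each selectivity is tested against the null-set window
    means; neurons selective for both are split by whether the *sum* of the
    two selectivities differs from its null (kernels that are mirror images
    pass as "both_equal_opposite").
    """
    lo, hi = window
    n_lags = len(kernel_in)
    if not (0 <= lo < hi <= n_lags) or hi > len(kernel_out):
        raise ValueError(f"window {window} outside kernel support")

    def _test(obs_kernel, null_set):
        sel = float(np.mean(obs_kernel[lo:hi]))
        null_means = null_set.kernels[:, lo:hi].mean(axis=1)
        sd = null_means.std(ddof=1)
        if sd == 0:
            return sel, np.nan
        t = (sel - null_means.mean()) / sd
        return sel, 2.0 * stats.t.sf(abs(t), df=len(null_means) - 1)

    sel_in, p_in = _test(np.asarray(kernel_in, float), null_in)
    sel_out, p_out = _test(np.asarray(kernel_out, float), null_out)
    sig_in = bool(p_in < alpha) if np.isfinite(p_in) else False
    sig_out = bool(p_out < alpha) if np.isfinite(p_out) else False

    p_sum = np.nan
    if sig_in and sig_out:
        obs_sum = sel_in + sel_out
        n = min(null_in.n_shuffles, null_out.n_shuffles)
        null_sum = (
            null_in.kernels[:n, lo:hi].mean(axis=1)
            + null_out.kernels[:n, lo:hi].mean(axis=1)
        )
        sd = null_sum.std(ddof=1)
        t = (obs_sum - null_sum.mean()) / sd if sd > 0 else np.inf
        p_sum = 2.0 * stats.t.sf(abs(t), df=n - 1)
        category = "both_different" if p_sum < alpha else "both_equal_opposite"
    elif sig_in:
        category = "in_only"
    elif sig_out:
        category = "out_only"
    else:
        category = "none"
    return {
        "category": category,
        "selectivity_in": sel_in,
        "selectivity_out": sel_out,
        "p_in": float(p_in),
        "p_out": float(p_out),
        "p_sum": float(p_sum),
    }


@dataclass
class Model2Fit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def model2_regression(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> Model2Fit:
    """Reduced-major-axis (model II) regression with permutation significance.

    slope = sign(r) * sd(y)/sd(x), intercept = mean(y) - slope*mean(x).
    The p value permutes y against x (the named procedure in the source
    literature is not fully specified; a permutation test stands in for it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float((np.sign(r) if r != 0 else 1.0) * sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(rp) >= abs(r):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return Model2Fit(slope=slope, intercept=intercept, r=r, p_value=float(p), n=len(x))
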