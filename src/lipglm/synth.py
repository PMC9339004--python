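"""Synthetic behavioral choices and spike trains with the statistical
structure the analyses assume.

The generator plays the role of the deposited dataset: a table of trials
(six-stimulus streams, T_in color, choice, delay, reward) plus per-neuron
10-ms binned spike counts, with known ground truth so that every stage of
the pipeline can be exercised and checked by parameter recovery.

Choices come from a base-10 logistic agent whose per-shape leverages play
the role of subjective weights. Spikes come from an inhomogeneous Poisson
process whose log rate is the same convolutional form the encoding model
fits (shared regressor code path), so forward simulation and fitting are
exact inverses of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from . import glm
from .task import (
    LN10,
    N_EPOCHS,
    N_SHAPES,
    RED,
    DerivedStimulusVars,
    ShapeSet,
    TaskConfig,
    Trial,
    assign_reward,
    derive_stimulus_vars,
    sample_trial,
)

__all__ = [
    "AgentSpec",
    "NeuronSpec",
    "SyntheticDataset",
    "NEURON_TEMPLATES",
    "simulate_choices",
    "make_neuron_spec",
    "combine_specs",
    "simulate_spike_counts",
    "generate_dataset",
]

#: Hard ceiling on the simulated rate (spikes/s); degenerate amplitudes are
#: clipped with a warning rather than overflowing exp().
MAX_RATE_SPS = 1000.0


@dataclass(frozen=True)
class AgentSpec:
    """A base-10 logistic chooser: P(red) = 1 / (1 + 10**-Q) with
    Q = bias + sum_i w_i (N_red_i - N_green_i)."""

    subjective_weights: Tuple[float, ...]
    bias: float = 0.0

    def __post_init__(self):
        w = tuple(float(x) for x in self.subjective_weights)
        if len(w) != N_SHAPES:
            raise ValueError(f"need {N_SHAPES} subjective weights")
        if not all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise ValueError("agent parameters must be finite")
        object.__setattr__(self, "subjective_weights", w)


@dataclass
class NeuronSpec:
    """Ground-truth generative parameters for one synthetic neuron."""

    baseline_log_rate: float              # log spikes/s
    kernels: Dict[str, np.ndarray]        # per-lag weights, 10-ms lags
    variable_set: str = "full"
    template: str = "null"

    def __post_init__(self):
        rate = float(np.exp(self.baseline_log_rate))
        if not 0.1 < rate < 200.0:
            raise ValueError(f"baseline rate {rate:.3g} sp/s outside (0.1, 200)")
        for v, k in self.kernels.items():
            expected = (
                glm.TARGET_SUPPORT if v in glm.TARGET_VARIABLES else glm.SHAPE_SUPPORT
            )
            if len(k) != expected:
                raise ValueError(f"kernel for {v!r} must have {expected} lags")


def simulate_choices(trials: Sequence[Trial], agent: AgentSpec, rng) -> List[Trial]:
    """Draw a choice per trial from the agent and return chosen trials.

    The leverage Q depends on how often each shape appears in red versus
    green, exactly mirroring the subjective-weight regression design.
    """
    rng = np.random.default_rng(rng)
    w = np.asarray(agent.subjective_weights)
    out = []
    for t in trials:
        counts = np.zeros(N_SHAPES)
        for s in t.stimuli:
            counts[s.shape_id - 1] += 1.0 if s.color == RED else -1.0
        q = agent.bias + counts @ w
        p_red = expit(LN10 * q)
        chosen = RED if rng.random() < p_red else "green"
        out.append(t.with_choice(chosen))
    return out


def _bump(n_lags: int, onset_ms: float, peak_ms: float, off_ms: float,
          amp: float, bin_ms: int = 10) -> np.ndarray:
    """Smooth transient: raised-cosine rise onset->peak, fall peak->off,
    exactly zero outside [onset, off]."""
    t = np.arange(n_lags) * bin_ms
    k = np.zeros(n_lags)
    rise = (t >= onset_ms) & (t < peak_ms)
    fall = (t >= peak_ms) & (t < off_ms)
    k[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset_ms) / (peak_ms - onset_ms)))
    k[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - peak_ms) / (off_ms - peak_ms)))
    return amp * k


def _ramp_plateau(n_lags: int, onset_ms: float, rise_ms: float, amp: float,
                  bin_ms: int = 10) -> np.ndarray:
    """Sustained response: zero before onset, smooth rise, flat to support end."""
    t = np.arange(n_lags) * bin_ms
    k = np.zeros(n_lags)
    rising = (t >= onset_ms) & (t < onset_ms + rise_ms)
    k[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - onset_ms) / rise_ms))
    k[t >= onset_ms + rise_ms] = 1.0
    return amp * k


#: template name -> (variable it loads, kernel builder)
NEURON_TEMPLATES = {
    "null": None,
    # negative transient peaking 200-400 ms, decayed to zero by 1000 ms
    "weight_neg_transient": ("weight", lambda a: _bump(150, 200, 300, 1000, -a)),
    # negative transient with a later onset (~350 ms)
    "consistency_route": ("consistency", lambda a: _bump(150, 350, 500, 1200, -a)),
    # same transient profile loaded on color evidence instead
    "color_evidence_route": ("color_evidence", lambda a: _bump(150, 350, 500, 1200, -a)),
    # positive sustained response, onset ~680 ms, held to the support end
    "evidence_sustained": ("evidence", lambda a: _ramp_plateau(150, 680, 200, a)),
}


def make_neuron_spec(
    template: str,
    amplitude: float = 0.3,
    baseline_rate: float = 20.0,
    variable_set: str = "full",
    rng=None,
    amplitude_jitter_sd: float = 0.0,
) -> NeuronSpec:
    """Build a ground-truth neuron from a named response template.

    Template onsets loosely mirror the latency ordering the analyses are
    meant to recover (weight before consistency before evidence); they are
    simulation conventions, not measurements. ``amplitude_jitter_sd``
    (lognormal sd on the amplitude) diversifies a cohort.
    """
    if template not in NEURON_TEMPLATES:
        raise KeyError(
            f"unknown template {template!r}; known: {sorted(NEURON_TEMPLATES)}"
        )
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    amp = float(amplitude)
    if amplitude_jitter_sd > 0:
        rng = np.random.default_rng(rng)
        amp *= float(np.exp(rng.normal(0.0, amplitude_jitter_sd)))
    kernels: Dict[str, np.ndarray] = {}
    if NEURON_TEMPLATES[template] is not None:
        variable, builder = NEURON_TEMPLATES[template]
        kernels[variable] = builder(amp)
    return NeuronSpec(
        baseline_log_rate=float(np.log(baseline_rate)),
        kernels=kernels,
        variable_set=variable_set,
        template=template,
    )


def combine_specs(specs: Sequence[NeuronSpec], baseline_rate: Optional[float] = None,
                  template: str = "combined") -> NeuronSpec:
    """Merge several single-variable templates into one neuron (kernels of
    the same variable add)."""
    if not specs:
        raise ValueError("need at least one spec")
    kernels: Dict[str, np.ndarray] = {}
    for s in specs:
        for v, k in s.kernels.items():
            kernels[v] = kernels.get(v, 0.0) + np.asarray(k, dtype=float)
    base = np.log(baseline_rate) if baseline_rate is not None else specs[0].baseline_log_rate
    return NeuronSpec(
        baseline_log_rate=float(base),
        kernels=kernels,
        variable_set=specs[0].variable_set,
        template=template,
    )


def simulate_spike_counts(
    neuron: NeuronSpec,
    trials: Sequence[Trial],
    derived_vars: Sequence[DerivedStimulusVars],
    task_config: Optional[TaskConfig] = None,
    rng=None,
    regressor_set: Optional[glm.RegressorSet] = None,
) -> List[np.ndarray]:
    """Inhomogeneous-Poisson spike counts from the neuron's generative model.

    The log rate is built through the same regressor code path the encoding
    model fits; counts in each 10-ms bin are Poisson with mean delta*lambda.
    Pass a prebuilt ``regressor_set`` to amortize design construction across
    neurons.
    """
    rng = np.random.default_rng(rng)
    rs = regressor_set
    if rs is None:
        rs = glm.build_regressors(
            trials, derived_vars, neuron.variable_set, task_config
        )
    model = glm.KernelModel(
        variables=rs.variables,
        intercept=neuron.baseline_log_rate,
        kernels={v: neuron.kernels.get(v, np.zeros(rs.kernel_lags(v))) for v in rs.variables},
        nll=np.nan,
        converged=True,
        n_iter=0,
    )
    eta = rs.matrix() @ model.coef_vector(rs)
    log_cap = np.log(MAX_RATE_SPS)
    if np.any(eta > log_cap):
        warnings.warn(
            f"simulated log-rate exceeds {MAX_RATE_SPS:.0f} sp/s; clipping",
            RuntimeWarning,
        )
        eta = np.minimum(eta, log_cap)
    lam = np.exp(eta)  # spikes/s
    counts = rng.poisson(rs.delta_s * lam)
    return [c.astype(np.int64) for c in rs.split_per_trial(counts)]


@dataclass
class SyntheticDataset:
    """A full synthetic session: trials with choices and rewards, per-neuron
    binned counts, and the ground truth that generated them."""

    trials: List[Trial]
    derived_vars: List[DerivedStimulusVars]
    counts: List[List[np.ndarray]]        # [neuron][trial] -> bins
    neuron_specs: List[NeuronSpec]
    agent: AgentSpec
    shape_set: ShapeSet
    task_config: TaskConfig
    master_seed: int

    def __post_init__(self):
        n_trials = len(self.trials)
        if len(self.derived_vars) != n_trials:
            raise ValueError("derived_vars/trials mismatch")
        for c in self.counts:
            if len(c) != n_trials:
                raise ValueError("every neuron needs counts for every trial")


def generate_dataset(
    n_neurons: int,
    n_trials: int,
    cohort: Optional[Dict[str, float]] = None,
    master_seed: int = 0,
    shape_set: Optional[ShapeSet] = None,
    task_config: Optional[TaskConfig] = None,
    agent: Optional[AgentSpec] = None,
    amplitude: float = 0.3,
    baseline_rate_range: Tuple[float, float] = (10.0, 40.0),
    variable_set: str = "full",
    out_dir=None,
) -> SyntheticDataset:
    """Generate a session emulating the deposited data's shape.

    ``cohort`` maps template names to fractions (default: half null, the
    rest split between weight-transient and sustained-evidence neurons).
    Per-neuron seeds are spawned deterministically from ``master_seed``.
    If ``out_dir`` is given the trial table, per-neuron count files, and a
    ground-truth record are written there (see :mod:`lipglm.io`).
    """
    if n_neurons < 1 or n_trials < 1:
        raise ValueError("need at least one neuron and one trial")
    shape_set = shape_set or ShapeSet()
    if shape_set.subjective_weights is None:
        # the agent's true leverages double as the subjective weights
        shape_set = shape_set.with_subjective(
            agent.subjective_weights if agent else shape_set.weights
        )
    task_config = task_config or TaskConfig()
    agent = agent or AgentSpec(shape_set.subjective_weights)
    cohort = cohort or {
        "null": 0.5,
        "weight_neg_transient": 0.25,
        "evidence_sustained": 0.25,
    }
    for name in cohort:
        if name not in NEURON_TEMPLATES:
            raise KeyError(f"unknown template {name!r} in cohort")

    ss = np.random.SeedSequence(master_seed)
    trial_seed, choice_seed, reward_seed, neuron_root = ss.spawn(4)
    trial_rng = np.random.default_rng(trial_seed)
    trials = [
        sample_trial(shape_set, task_config, trial_rng, trial_id=i)
        for i in range(n_trials)
    ]
    trials = simulate_choices(trials, agent, np.random.default_rng(choice_seed))
    reward_rng = np.random.default_rng(reward_seed)
    trials = [t.with_reward(assign_reward(t, task_config, reward_rng)) for t in trials]
    dvs = [derive_stimulus_vars(t, shape_set, use_subjective=True) for t in trials]

    # deterministic template assignment: largest-remainder apportionment
    names = sorted(cohort)
    fracs = np.array([cohort[n] for n in names], dtype=float)
    fracs = fracs / fracs.sum()
    base = np.floor(fracs * n_neurons).astype(int)
    for i in np.argsort(-(fracs * n_neurons - base))[: n_neurons - base.sum()]:
        base[i] += 1
    assignment = [n for n, k in zip(names, base) for _ in range(k)]

    rs = glm.build_regressors(trials, dvs, variable_set, task_config)
    specs: List[NeuronSpec] = []
    counts: List[List[np.ndarray]] = []
    for i, (template, child) in enumerate(zip(assignment, neuron_root.spawn(n_neurons))):
        rng = np.random.default_rng(child)
        baseline = float(rng.uniform(*baseline_rate_range))
        spec = make_neuron_spec(
            template,
            amplitude=amplitude,
            baseline_rate=baseline,
            variable_set=variable_set,
            rng=rng,
            amplitude_jitter_sd=0.2 if template != "null" else 0.0,
        )
        specs.append(spec)
        counts.append(
            simulate_spike_counts(spec, trials, dvs, task_config, rng, regressor_set=rs)
        )

    ds = SyntheticDataset(
        trials=trials,
        derived_vars=dvs,
        counts=counts,
        neuron_specs=specs,
        agent=agent,
        shape_set=shape_set,
        task_config=task_config,
        master_seed=master_seed,
    )
    if out_dir is not None:
        from . import io as lio

        lio.write_dataset(ds, out_dir)
    return ds
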