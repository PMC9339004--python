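"""Task structure for the sequential probabilistic-cue saccade task.

A trial presents six colored shapes in sequence. Each shape carries an
assigned weight ``W`` on the base-10 log-odds scale; the reward probability
of the red (green) target is the base-10 logistic of the summed weights of
the red (green) shapes. One target sits inside the recorded neuron's
response field (``T_in``); its color varies trial by trial.

This module owns the timing constants, the trial container, and the algebra
mapping each stimulus to the regressor variables used by the encoding model:

==============  =========================================================
variable        definition
==============  =========================================================
weight (SW)     the shape's (subjective) weight
color           +1 red, -1 green
consistency     +1 iff stimulus color equals T_in's color
evidence        SW x consistency (evidence for T_in)
color_evidence  SW x color (evidence for the red target)
sw_in / sw_out  SW routed to the T_in- / T_out-colored target, else 0
==============  =========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "RED",
    "GREEN",
    "COLOR_SIGN",
    "DEFAULT_SHAPE_WEIGHTS",
    "ShapeSet",
    "TaskConfig",
    "StimulusEvent",
    "Trial",
    "DerivedStimulusVars",
    "TrialTimeline",
    "reward_probability",
    "weight_sum_from_probability",
    "sample_trial",
    "assign_reward",
    "derive_stimulus_vars",
    "accumulated_evidence",
    "trial_timeline",
]

RED = "red"
GREEN = "green"
COLOR_SIGN = {RED: +1, GREEN: -1}
LN10 = math.log(10.0)

N_EPOCHS = 6
N_SHAPES = 6

#: Default assigned weights (base-10 log odds), symmetric, spanning weak to
#: strong cues. Shape ids 1..6 map to these in order.
DEFAULT_SHAPE_WEIGHTS: Tuple[float, ...] = (-0.9, -0.5, -0.3, 0.3, 0.5, 0.9)


@dataclass(frozen=True)
class ShapeSet:
    """The pool of six shapes with assigned (and optional subjective) weights.

    Parameters
    ----------
    weights
        Assigned weight per shape, indexed by ``shape_id - 1``.
    subjective_weights
        Behaviorally estimated leverage per shape (same indexing); optional.
    """

    weights: Tuple[float, ...] = DEFAULT_SHAPE_WEIGHTS
    subjective_weights: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) != N_SHAPES:
            raise ValueError(f"need exactly {N_SHAPES} shape weights, got {len(w)}")
        if not all(math.isfinite(x) for x in w):
            raise ValueError("shape weights must be finite")
        object.__setattr__(self, "weights", w)
        if self.subjective_weights is not None:
            sw = tuple(float(x) for x in self.subjective_weights)
            if len(sw) != N_SHAPES:
                raise ValueError("need one subjective weight per shape")
            if not all(math.isfinite(x) for x in sw):
                raise ValueError("subjective weights must be finite")
            object.__setattr__(self, "subjective_weights", sw)

    def weight_of(self, shape_id: int) -> float:
        if not 1 <= shape_id <= N_SHAPES:
            raise ValueError(f"unknown shape_id {shape_id}")
        return self.weights[shape_id - 1]

    def subjective_weight_of(self, shape_id: int) -> float:
        if self.subjective_weights is None:
            raise ValueError("subjective weights not set on this ShapeSet")
        if not 1 <= shape_id <= N_SHAPES:
            raise ValueError(f"unknown shape_id {shape_id}")
        return self.subjective_weights[shape_id - 1]

    def with_subjective(self, sw: Sequence[float]) -> "ShapeSet":
        return ShapeSet(self.weights, tuple(float(x) for x in sw))


@dataclass(frozen=True)
class TaskConfig:
    """Trial timing and reward scheme.

    Times are in ms. The trial clock used throughout starts at target onset
    (t = 0); the first stimulus appears ``t_first_stim_ms`` later and the six
    stimuli repeat with pitch ``stim_on_ms + stim_gap_ms``.
    """

    t_targets_ms: int = 567
    t_first_stim_ms: int = 533
    stim_on_ms: int = 333
    stim_gap_ms: int = 133
    end_delay_choices_ms: Tuple[int, ...] = (433, 533, 633)
    #: "probabilistic": large reward w.p. P(chosen), else small, for any choice.
    #: "better_only": that lottery only when the better target was chosen.
    reward_scheme: str = "probabilistic"
    large_reward_ul: float = 240.0
    small_reward_ul: float = 60.0
    #: If True the better_only scheme gives a small reward (not none) for the
    #: worse choice.
    better_only_small_for_worse: bool = False

    def __post_init__(self):
        for name in ("t_targets_ms", "t_first_stim_ms", "stim_on_ms", "stim_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.end_delay_choices_ms or any(d <= 0 for d in self.end_delay_choices_ms):
            raise ValueError("end delays must be positive")
        if self.reward_scheme not in ("probabilistic", "better_only"):
            raise ValueError(f"unknown reward scheme {self.reward_scheme!r}")

    @property
    def epoch_pitch_ms(self) -> int:
        return self.stim_on_ms + self.stim_gap_ms

    def stim_onset_ms(self, epoch: int) -> int:
        if not 1 <= epoch <= N_EPOCHS:
            raise ValueError(f"epoch must be 1..{N_EPOCHS}, got {epoch}")
        return self.t_first_stim_ms + (epoch - 1) * self.epoch_pitch_ms

    def trial_length_ms(self, end_delay_ms: int) -> int:
        """Target onset to go cue (fixation off)."""
        return self.t_first_stim_ms + N_EPOCHS * self.epoch_pitch_ms + end_delay_ms


@dataclass(frozen=True)
class StimulusEvent:
    epoch: int
    shape_id: int
    color: str
    onset_ms: int

    def __post_init__(self):
        if not 1 <= self.epoch <= N_EPOCHS:
            raise ValueError(f"epoch must be 1..{N_EPOCHS}")
        if self.color not in COLOR_SIGN:
            raise ValueError(f"color must be 'red' or 'green', got {self.color!r}")


@dataclass(frozen=True)
class Trial:
    """One behavioral trial: six stimuli, target configuration, choice, reward."""

    trial_id: int
    stimuli: Tuple[StimulusEvent, ...]
    tin_color: str
    end_delay_ms: int
    p_red: float
    p_green: float
    choice: Optional[str] = None        # "T_in" | "T_out"
    chosen_color: Optional[str] = None  # "red" | "green"
    reward: Optional[str] = None        # "large" | "small" | "none"

    def __post_init__(self):
        if len(self.stimuli) != N_EPOCHS:
            raise ValueError(f"a trial has exactly {N_EPOCHS} stimuli")
        if self.tin_color not in COLOR_SIGN:
            raise ValueError("tin_color must be 'red' or 'green'")
        if not (0.0 < self.p_red < 1.0 and 0.0 < self.p_green < 1.0):
            raise ValueError("reward probabilities must lie in (0, 1)")
        if (self.choice is None) != (self.chosen_color is None):
            raise ValueError("choice and chosen_color must be set together")
        if self.choice is not None:
            if self.choice not in ("T_in", "T_out"):
                raise ValueError("choice must be 'T_in' or 'T_out'")
            expected = self.tin_color if self.choice == "T_in" else _other(self.tin_color)
            if self.chosen_color != expected:
                raise ValueError("chosen_color inconsistent with choice and tin_color")

    @property
    def configuration(self) -> int:
        """+1 iff T_in is red."""
        return COLOR_SIGN[self.tin_color]

    def with_choice(self, chosen_color: str) -> "Trial":
        choice = "T_in" if chosen_color == self.tin_color else "T_out"
        return replace(self, choice=choice, chosen_color=chosen_color)

    def with_reward(self, reward: str) -> "Trial":
        return replace(self, reward=reward)


@dataclass(frozen=True)
class DerivedStimulusVars:
    """Per-stimulus regressor values for one trial (arrays of length 6)."""

    sw: np.ndarray
    color: np.ndarray
    consistency: np.ndarray
    color_evidence: np.ndarray
    evidence: np.ndarray
    sw_in: np.ndarray
    sw_out: np.ndarray
    configuration: int


def _other(color: str) -> str:
    return GREEN if color == RED else RED


def reward_probability(weight_sum):
    """Reward probability from summed weights: ``10**s / (1 + 10**s)``.

    Accepts scalars or arrays; strictly increasing, maps the reals onto (0, 1).
    """
    s = np.asarray(weight_sum, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("weight sum must be finite")
    p = expit(LN10 * s)
    return float(p) if np.isscalar(weight_sum) or s.ndim == 0 else p


def weight_sum_from_probability(p):
    """Inverse of :func:`reward_probability`: ``log10(p / (1 - p))``."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("probability must lie in (0, 1)")
    s = logit(arr) / LN10
    return float(s) if np.isscalar(p) or arr.ndim == 0 else s


def sample_trial(shape_set: ShapeSet, config: TaskConfig, rng, trial_id: int = 0) -> Trial:
    """Draw one trial: shapes i.i.d. uniform over the pool, colors i.i.d.
    uniform over red/green, T_in color uniform, end delay uniform.

    ``rng`` may be an integer seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng)
    shape_ids = rng.integers(1, N_SHAPES + 1, size=N_EPOCHS)
    colors = np.where(rng.random(N_EPOCHS) < 0.5, RED, GREEN)
    tin_color = RED if rng.random() < 0.5 else GREEN
    end_delay = int(rng.choice(config.end_delay_choices_ms))
    stimuli = tuple(
        StimulusEvent(
            epoch=k + 1,
            shape_id=int(shape_ids[k]),
            color=str(colors[k]),
            onset_ms=config.stim_onset_ms(k + 1),
        )
        for k in range(N_EPOCHS)
    )
    red_sum = sum(shape_set.weight_of(s.shape_id) for s in stimuli if s.color == RED)
    green_sum = sum(shape_set.weight_of(s.shape_id) for s in stimuli if s.color == GREEN)
    return Trial(
        trial_id=trial_id,
        stimuli=stimuli,
        tin_color=tin_color,
        end_delay_ms=end_delay,
        p_red=reward_probability(red_sum),
        p_green=reward_probability(green_sum),
    )


def assign_reward(trial: Trial, config: TaskConfig, rng) -> str:
    """Draw the reward outcome for a chosen trial.

    probabilistic scheme: large w.p. P(chosen target), else small.
    better_only scheme: the same lottery if the chosen target has the
    (weakly) higher reward probability, otherwise no reward (or a small one,
    per ``config.better_only_small_for_worse``).
    """
    if trial.choice is None:
        raise ValueError("trial has no choice; cannot assign reward")
    rng = np.random.default_rng(rng)
    p_chosen = trial.p_red if trial.chosen_color == RED else trial.p_green
    p_other = trial.p_green if trial.chosen_color == RED else trial.p_red
    if config.reward_scheme == "better_only" and p_chosen < p_other:
        return "small" if config.better_only_small_for_worse else "none"
    return "large" if rng.random() < p_chosen else "small"


def derive_stimulus_vars(
    trial: Trial, shape_set: ShapeSet, use_subjective: bool = True
) -> DerivedStimulusVars:
    """Map the six stimuli of a trial to the encoding-model variables.

    With ``use_subjective`` the subjective weights stand in for the assigned
    ones (they must be present on the shape set).
    """
    if use_subjective:
        sw = np.array(
            [shape_set.subjective_weight_of(s.shape_id) for s in trial.stimuli]
        )
    else:
        sw = np.array([shape_set.weight_of(s.shape_id) for s in trial.stimuli])
    color = np.array([COLOR_SIGN[s.color] for s in trial.stimuli], dtype=float)
    cfg = trial.configuration
    consistency = color * cfg
    evidence = sw * consistency
    color_evidence = sw * color
    sw_in = np.where(consistency > 0, sw, 0.0)
    sw_out = np.where(consistency < 0, sw, 0.0)
    return DerivedStimulusVars(
        sw=sw,
        color=color,
        consistency=consistency,
        color_evidence=color_evidence,
        evidence=evidence,
        sw_in=sw_in,
        sw_out=sw_out,
        configuration=cfg,
    )


def accumulated_evidence(dsv: DerivedStimulusVars, through_epoch: int) -> float:
    """Running evidence for T_in through the given epoch: sum of sw_in - sw_out."""
    if not 1 <= through_epoch <= N_EPOCHS:
        raise ValueError(f"epoch must be 1..{N_EPOCHS}, got {through_epoch}")
    k = through_epoch
    return float(np.sum(dsv.sw_in[:k]) - np.sum(dsv.sw_out[:k]))


@dataclass(frozen=True)
class TrialTimeline:
    """Event-to-bin map on a clock with t = 0 at target onset.

    Bins are 0-based and half-open, ``[t, t + bin_ms)``; event times are
    floored onto the grid. The model window runs from target onset to the go
    cue (fixation off).
    """

    bin_ms: int
    n_bins: int
    target_onset_bin: int
    stim_onset_bins: Tuple[int, ...]

    def bin_of(self, t_ms: float) -> int:
        return int(t_ms // self.bin_ms)


def trial_timeline(trial: Trial, config: TaskConfig, bin_ms: int = 10) -> TrialTimeline:
    if not (isinstance(bin_ms, (int, np.integer)) and bin_ms > 0):
        raise ValueError(f"bin_ms must be a positive integer, got {bin_ms!r}")
    total_ms = config.trial_length_ms(trial.end_delay_ms)
    if bin_ms > config.stim_gap_ms:
        raise ValueError("bin_ms too coarse for the task's event spacing")
    return TrialTimeline(
        bin_ms=int(bin_ms),
        n_bins=total_ms // bin_ms,
        target_onset_bin=0,
        stim_onset_bins=tuple(config.stim_onset_ms(k) // bin_ms for k in range(1, N_EPOCHS + 1)),
    )
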