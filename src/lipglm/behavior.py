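"""Behavioral analyses: subjective weights, epoch leverage, psychometrics.

Choices are modeled with a base-10 logistic, P(choice = red) = 1/(1 + 10**-Q),
so that the fitted coefficients live on the same log10-odds scale as the
assigned shape weights. Q is a linear function of the trial's stimuli:

* subjective weights: one coefficient per shape, multiplying how often the
  shape appeared in red minus how often in green;
* epoch leverage: one coefficient per presentation epoch, multiplying the
  epoch stimulus's subjective weight signed by its color.

Base-10 coefficients are natural-log logistic coefficients divided by ln 10;
the fit here maximizes the base-10 likelihood directly with Newton's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import expit

from .task import (
    GREEN,
    LN10,
    N_EPOCHS,
    N_SHAPES,
    RED,
    COLOR_SIGN,
    ShapeSet,
    Trial,
)

__all__ = [
    "SeparationError",
    "LogisticFit",
    "SubjectiveWeightFit",
    "EpochLeverageFit",
    "fit_base10_logistic",
    "fit_subjective_weights",
    "fit_epoch_leverage",
    "psychometric_curve",
    "choices_as_red_indicator",
]


class SeparationError(ValueError):
    """The likelihood has no finite maximizer (perfectly separated data)."""


@dataclass
class LogisticFit:
    """Base-10 logistic ML fit with Wald standard errors."""

    coef: np.ndarray
    se: np.ndarray
    llf: float          # natural-log likelihood at the optimum
    n_obs: int
    n_iter: int
    converged: bool

    @property
    def pvalues(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class SubjectiveWeightFit:
    bias: float
    weights: np.ndarray        # one per shape
    bias_se: float
    weights_se: np.ndarray
    llf: float
    n_trials: int
    pvalues: np.ndarray        # per shape, two-tailed Wald


@dataclass
class EpochLeverageFit:
    bias: float
    leverage: np.ndarray       # one per epoch
    bias_se: float
    leverage_se: np.ndarray
    llf: float
    n_trials: int
    pvalues: np.ndarray


def choices_as_red_indicator(trials: Sequence[Trial]) -> np.ndarray:
    """1 where the red target was chosen, 0 where green."""
    y = np.empty(len(trials))
    for i, t in enumerate(trials):
        if t.chosen_color is None:
            raise ValueError(f"trial {t.trial_id} has no choice")
        y[i] = 1.0 if t.chosen_color == RED else 0.0
    return y


def _collinear_columns(X: np.ndarray) -> List[int]:
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 1.0)
    return [int(i) for i in np.where(d < tol)[0]]

def fit_base10_logistic(
    design: np.ndarray,
    choices: np.ndarray,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> LogisticFit:
    """Maximum-likelihood Bernoulli fit with a base-10 logit link.

    ``design`` holds one row of leverages per trial; ``choices`` is the 0/1
    outcome (red chosen). Standard errors come from the observed information
    on the base-10 scale. Perfect separation and rank deficiency raise.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    y = np.asarray(choices, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("design/choices length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("choices must be coded 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if y.min() == y.max():
        raise SeparationError("all choices identical; no finite ML estimate")
    bad = _collinear_columns(X)
    if bad:
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = LN10 * (X @ beta)
        p = expit(eta)
        grad = LN10 * (X.T @ (p - y))
        w = p * (1.0 - p)
        H = LN10**2 * (X.T * w) @ X
        if np.linalg.norm(beta, np.inf) > 1e4:
            raise SeparationError(
                "coefficients diverging: data are perfectly separated"
            )
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix singular (fitted probabilities saturated)"
            )
        beta_new = beta - step
        if np.linalg.norm(step, np.inf) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = LN10 * (X @ beta)
    p = expit(eta)
    if np.any((p < 1e-12) & (y == 1)) or np.any((p > 1 - 1e-12) & (y == 0)):
        raise SeparationError("fitted probabilities saturated at the data")
    w = p * (1.0 - p)
    H = LN10**2 * (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    llf = float(np.sum(y * np.log(np.clip(p, 1e-300, 1)) +
                       (1 - y) * np.log(np.clip(1 - p, 1e-300, 1))))
    return LogisticFit(coef=beta, se=se, llf=llf, n_obs=len(y),
                       n_iter=it, converged=converged)


def subjective_weight_design(trials: Sequence[Trial]) -> np.ndarray:
    """Row per trial: N_red_i - N_green_i for each shape i (no intercept col)."""
    X = np.zeros((len(trials), N_SHAPES))
    for r, t in enumerate(trials):
        for s in t.stimuli:
            X[r, s.shape_id - 1] += 1.0 if s.color == RED else -1.0
    return X


def fit_subjective_weights(
    trials: Sequence[Trial], choices: Optional[np.ndarray] = None
) -> SubjectiveWeightFit:
    """Estimate each shape's leverage on choice (its subjective weight)."""
    y = choices_as_red_indicator(trials) if choices is None else np.asarray(choices, float)
    X = subjective_weight_design(trials)
    fit = fit_base10_logistic(X, y)
    return SubjectiveWeightFit(
        bias=float(fit.coef[0]),
        weights=fit.coef[1:],
        bias_se=float(fit.se[0]),
        weights_se=fit.se[1:],
        llf=fit.llf,
        n_trials=fit.n_obs,
        pvalues=fit.pvalues[1:],
    )


def epoch_leverage_design(
    trials: Sequence[Trial], subjective_weights: Sequence[float]
) -> np.ndarray:
    """Row per trial: SW_red_i - SW_green_i per epoch i, i.e. the epoch
    stimulus's subjective weight signed by its color (+red / -green)."""
    sw = np.asarray(subjective_weights, dtype=float)
    if len(sw) != N_SHAPES:
        raise ValueError(f"need {N_SHAPES} subjective weights")
    X = np.zeros((len(trials), N_EPOCHS))
    for r, t in enumerate(trials):
        for s in t.stimuli:
            X[r, s.epoch - 1] = sw[s.shape_id - 1] * COLOR_SIGN[s.color]
    return X


def fit_epoch_leverage(
    trials: Sequence[Trial],
    choices: Optional[np.ndarray] = None,
    subjective_weights: Optional[Sequence[float]] = None,
) -> EpochLeverageFit:
    """One leverage coefficient per presentation epoch; equal coefficients
    mean every epoch influenced the choice equally."""
    if subjective_weights is None:
        subjective_weights = fit_subjective_weights(trials, choices).weights
    y = choices_as_red_indicator(trials) if choices is None else np.asarray(choices, float)
    X = epoch_leverage_design(trials, subjective_weights)
    fit = fit_base10_logistic(X, y)
    return EpochLeverageFit(
        bias=float(fit.coef[0]),
        leverage=fit.coef[1:],
        bias_se=float(fit.se[0]),
        leverage_se=fit.se[1:],
        llf=fit.llf,
        n_trials=fit.n_obs,
        pvalues=fit.pvalues[1:],
    )


def psychometric_curve(
    trials: Sequence[Trial],
    choices: Optional[np.ndarray] = None,
    n_bins: int = 9,
    shape_set: Optional[ShapeSet] = None,
) -> dict:
    """Choice fraction versus net assigned evidence, in equal-count bins.

    The abscissa is the trial's total red-shape weight minus total
    green-shape weight; each bin reports the mean abscissa, the fraction of
    red choices, and its binomial standard error.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(trials) < n_bins:
        raise ValueError(f"need at least {n_bins} trials for {n_bins} bins")
    shape_set = shape_set or ShapeSet()
    y = choices_as_red_indicator(trials) if choices is None else np.asarray(choices, float)
    x = np.array(
        [
            sum(
                shape_set.weight_of(s.shape_id) * COLOR_SIGN[s.color]
                for s in t.stimuli
            )
            for t in trials
        ]
    )
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, n_bins)
    mean_x = np.array([x[b].mean() for b in bins])
    p_red = np.array([y[b].mean() for b in bins])
    n = np.array([len(b) for b in bins])
    se = np.sqrt(p_red * (1 - p_red) / n)
    return {"evidence": mean_x, "p_red": p_red, "se": se, "n": n}
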