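"""Convolutional Poisson GLM for trial-aligned spike counts.

The model treats the spike count in each 10-ms bin as Poisson with rate

    lambda_t = exp( b0 + sum_i (k_i * f(x_i))(t) )        [spikes/s]

where each task variable x_i enters as an event-locked time course f(x_i)
and k_i is a per-lag response kernel. Kernels for stimulus-locked variables
span 1500 ms (150 lags); kernels for the target-locked variables span
3000 ms (300 lags). Contributions extending past the go cue are truncated.

Two regressor modes are provided:

* ``impulse`` (default): f(x_i) places an impulse of amplitude x_i at each
  event-onset bin; the per-lag kernel carries the full temporal profile.
* ``boxcar``: f(x_i) holds the amplitude for the variable's support from
  onset (a literal boxcar), convolved with a shorter free kernel.

Fitting maximizes the Poisson likelihood, with no regularization, by damped
Newton iterations on the (convex) negative log-likelihood using the exact
sparse-design Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .task import (
    N_EPOCHS,
    DerivedStimulusVars,
    TaskConfig,
    Trial,
    trial_timeline,
)

__all__ = [
    "VARIABLE_SETS",
    "SHAPE_SUPPORT",
    "TARGET_SUPPORT",
    "RegressorSet",
    "KernelModel",
    "FitConfig",
    "DegenerateDataError",
    "build_regressors",
    "nll_and_gradient",
    "fit_kernels",
    "predict_rate",
    "crossvalidate",
    "intercept_only_nll",
]

#: Kernel support in 10-ms lags.
SHAPE_SUPPORT = 150   # 1500 ms for stimulus-locked variables
TARGET_SUPPORT = 300  # 3000 ms for target-locked variables

TARGET_VARIABLES = ("target_onset", "target_config")

VARIABLE_SETS: Dict[str, Tuple[str, ...]] = {
    # The 8-variable model used for the weight / evidence / route analyses.
    "full": (
        "stimulus_onset",
        "weight",
        "color",
        "evidence",
        "consistency",
        "color_evidence",
        "target_onset",
        "target_config",
    ),
    # The 4-variable model splitting a stimulus's weight by target routing.
    "sw_in_out": ("stimulus_onset", "color", "sw_in", "sw_out"),
}


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the model (e.g. zero spikes)."""


def _stim_values(dsv: DerivedStimulusVars, variable: str) -> np.ndarray:
    if variable == "stimulus_onset":
        return np.ones(N_EPOCHS)
    if variable == "weight":
        return dsv.sw
    return getattr(dsv, variable)


@dataclass
class RegressorSet:
    """Event-locked regressors for a set of trials, as a lazily-built sparse
    design matrix plus the event bookkeeping needed to permute a variable's
    per-trial values across trials (event times kept)."""

    variables: Tuple[str, ...]
    supports: Dict[str, int]
    values: Dict[str, np.ndarray]       # variable -> (n_trials, n_events) amplitudes
    trial_lens: np.ndarray              # bins per trial
    stim_onset_bins: Tuple[int, ...]
    bin_ms: int = 10
    mode: str = "impulse"
    boxcar_kernel_support: int = 50

    def __post_init__(self):
        self.trial_lens = np.asarray(self.trial_lens, dtype=np.int64)
        self.trial_starts = np.concatenate(([0], np.cumsum(self.trial_lens)[:-1]))
        self.n_trials = len(self.trial_lens)
        self.n_bins_total = int(self.trial_lens.sum())
        self.col_slices: Dict[str, slice] = {}
        c = 1  # column 0 is the intercept
        for v in self.variables:
            L = self.supports[v]
            self.col_slices[v] = slice(c, c + L)
            c += L
        self.n_cols = c
        self._pattern = None
        self._X_cache = None

    @property
    def delta_s(self) -> float:
        """Bin width in seconds (the Poisson exposure per bin)."""
        return self.bin_ms / 1000.0

    # -- design construction ------------------------------------------------

    def _event_table(self, variable: str) -> Tuple[np.ndarray, np.ndarray]:
        """(onset_bins, amp_flat_index) per event, over all trials."""
        vals = self.values[variable]
        n_events = vals.shape[1]
        if variable in TARGET_VARIABLES:
            onsets = np.zeros(n_events, dtype=np.int64)
        else:
            onsets = np.asarray(self.stim_onset_bins[:n_events], dtype=np.int64)
        trial_idx = np.repeat(np.arange(self.n_trials), n_events)
        ev_onset = self.trial_starts[trial_idx] + np.tile(onsets, self.n_trials)
        amp_idx = np.arange(self.n_trials * n_events)
        trial_end = self.trial_starts[trial_idx] + self.trial_lens[trial_idx]
        return ev_onset, amp_idx, trial_end

    def _build_pattern(self):
        """COO pattern (rows, cols, amp ids) for every variable, built once."""
        rows_all, cols_all, amp_all, var_all = [], [], [], []
        for vi, v in enumerate(self.variables):
            L = self.supports[v]
            kernel_lags = L if self.mode == "impulse" else self.boxcar_kernel_support
            box_len = 1 if self.mode == "impulse" else L
            ev_onset, amp_idx, trial_end = self._event_table(v)
            c0 = self.col_slices[v].start
            # entry for (event e, lag l, boxcar offset d): row = onset + l + d
            lags = np.arange(kernel_lags, dtype=np.int64)
            offs = np.arange(box_len, dtype=np.int64)
            shift = (lags[:, None] + offs[None, :]).ravel()          # (Lk*box,)
            col_l = np.repeat(lags, box_len)
            rows = ev_onset[:, None] + shift[None, :]                # (E, Lk*box)
            cols = c0 + np.broadcast_to(col_l, rows.shape)
            amps = np.broadcast_to(amp_idx[:, None], rows.shape)
            valid = rows < trial_end[:, None]
            rows_all.append(rows[valid])
            cols_all.append(cols[valid])
            amp_all.append(amps[valid])
            var_all.append(np.full(valid.sum(), vi, dtype=np.int32))
        self._pattern = (
            np.concatenate(rows_all),
            np.concatenate(cols_all),
            np.concatenate(amp_all),
            np.concatenate(var_all),
        )

    def matrix(self, overrides: Optional[Dict[str, np.ndarray]] = None) -> sparse.csr_matrix:
        """Sparse design matrix (n_bins_total x n_cols), intercept in column 0.

        ``overrides`` replaces a variable's per-trial value array (same shape),
        e.g. with a trial-permuted copy, without touching event times.
        """
        if overrides is None and self._X_cache is not None:
            return self._X_cache
        if self._pattern is None:
            self._build_pattern()
        rows, cols, amp_idx, var_idx = self._pattern
        data = np.empty(len(rows))
        for vi, v in enumerate(self.variables):
            vals = self.values[v]
            if overrides and v in overrides:
                vals = np.asarray(overrides[v], dtype=float)
                if vals.shape != self.values[v].shape:
                    raise ValueError(f"override for {v!r} has wrong shape")
            sel = var_idx == vi
            data[sel] = vals.ravel()[amp_idx[sel]]
        ones = np.ones(self.n_bins_total)
        rows = np.concatenate([np.arange(self.n_bins_total), rows])
        cols = np.concatenate([np.zeros(self.n_bins_total, dtype=np.int64), cols])
        data = np.concatenate([ones, data])
        X = sparse.coo_matrix(
            (data, (rows, cols)), shape=(self.n_bins_total, self.n_cols)
        ).tocsr()
        if overrides is None:
            self._X_cache = X
        return X

    def permuted_values(self, variable: str, perm: np.ndarray) -> Dict[str, np.ndarray]:
        """Override dict with ``variable``'s per-trial values permuted across
        trials (the shuffle used by the significance and CPD machinery)."""
        if variable not in self.values:
            raise KeyError(f"unknown variable {variable!r}")
        return {variable: self.values[variable][np.asarray(perm)]}

    def subset(self, trial_indices: Sequence[int]) -> "RegressorSet":
        idx = np.asarray(trial_indices)
        return RegressorSet(
            variables=self.variables,
            supports=dict(self.supports),
            values={v: a[idx] for v, a in self.values.items()},
            trial_lens=self.trial_lens[idx],
            stim_onset_bins=self.stim_onset_bins,
            bin_ms=self.bin_ms,
            mode=self.mode,
            boxcar_kernel_support=self.boxcar_kernel_support,
        )

    def kernel_lags(self, variable: str) -> int:
        if self.mode == "impulse":
            return self.supports[variable]
        return self.boxcar_kernel_support

    def flatten_counts(self, counts: Sequence[np.ndarray]) -> np.ndarray:
        if len(counts) != self.n_trials:
            raise ValueError("counts/trials length mismatch")
        lens = np.array([len(c) for c in counts])
        if not np.array_equal(lens, self.trial_lens):
            raise ValueError("per-trial count lengths do not match the timeline")
        y = np.concatenate([np.asarray(c) for c in counts]).astype(float)
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("counts must be non-negative integers")
        return y

    def split_per_trial(self, flat: np.ndarray) -> List[np.ndarray]:
        return np.split(np.asarray(flat), np.cumsum(self.trial_lens)[:-1])


def build_regressors(
    trials: Sequence[Trial],
    derived_vars: Sequence[DerivedStimulusVars],
    variable_set: str | Sequence[str] = "full",
    task_config: Optional[TaskConfig] = None,
    regressor_mode: str = "impulse",
    bin_ms: int = 10,
    shape_support: int = SHAPE_SUPPORT,
    target_support: int = TARGET_SUPPORT,
    boxcar_kernel_support: int = 50,
) -> RegressorSet:
    """Build the event-locked regressors for a trial set.

    ``variable_set`` is a named set (``"full"`` or ``"sw_in_out"``) or an
    explicit sequence of variable names.
    """
    if task_config is None:
        task_config = TaskConfig()
    if isinstance(variable_set, str):
        try:
            variables = VARIABLE_SETS[variable_set]
        except KeyError:
            raise KeyError(
                f"unknown variable set {variable_set!r}; "
                f"known: {sorted(VARIABLE_SETS)} or pass variable names"
            )
    else:
        variables = tuple(variable_set)
    known = set(VARIABLE_SETS["full"]) | set(VARIABLE_SETS["sw_in_out"])
    for v in variables:
        if v not in known:
            raise KeyError(f"unknown variable {v!r}")
    if regressor_mode not in ("impulse", "boxcar"):
        raise ValueError(f"unknown regressor_mode {regressor_mode!r}")
    if len(trials) != len(derived_vars):
        raise ValueError("trials and derived_vars length mismatch")

    timelines = [trial_timeline(t, task_config, bin_ms) for t in trials]
    trial_lens = np.array([tl.n_bins for tl in timelines])
    stim_onset_bins = timelines[0].stim_onset_bins

    values: Dict[str, np.ndarray] = {}
    for v in variables:
        if v == "target_onset":
            values[v] = np.ones((len(trials), 1))
        elif v == "target_config":
            values[v] = np.array([[float(t.configuration)] for t in trials])
        else:
            values[v] = np.stack([_stim_values(d, v) for d in derived_vars])

    supports = {
        v: (target_support if v in TARGET_VARIABLES else shape_support)
        for v in variables
    }
    return RegressorSet(
        variables=variables,
        supports=supports,
        values=values,
        trial_lens=trial_lens,
        stim_onset_bins=stim_onset_bins,
        bin_ms=bin_ms,
        mode=regressor_mode,
        boxcar_kernel_support=boxcar_kernel_support,
    )


@dataclass
class KernelModel:
    """Fitted kernels: intercept (log spikes/s), per-variable per-lag weights,
    the attained NLL, and fit diagnostics."""

    variables: Tuple[str, ...]
    intercept: float
    kernels: Dict[str, np.ndarray]
    nll: float
    converged: bool
    n_iter: int
    cv_results: Optional[dict] = None

    def coef_vector(self, rs: RegressorSet) -> np.ndarray:
        beta = np.zeros(rs.n_cols)
        beta[0] = self.intercept
        for v in rs.variables:
            k = self.kernels.get(v)
            sl = rs.col_slices[v]
            if k is not None:
                lags = rs.kernel_lags(v)
                if len(k) != lags:
                    raise ValueError(f"kernel for {v!r} has wrong length")
                beta[sl.start : sl.start + lags] = k
        return beta

    @classmethod
    def from_vector(cls, beta, rs: RegressorSet, nll, converged, n_iter) -> "KernelModel":
        kernels = {
            v: np.array(beta[rs.col_slices[v].start : rs.col_slices[v].start + rs.kernel_lags(v)])
            for v in rs.variables
        }
        return cls(
            variables=rs.variables,
            intercept=float(beta[0]),
            kernels=kernels,
            nll=float(nll),
            converged=bool(converged),
            n_iter=int(n_iter),
        )


@dataclass(frozen=True)
class FitConfig:
    max_iter: int = 100
    tol_nll: float = 1e-9    # relative NLL change
    tol_grad: float = 1e-6   # l2 norm of the gradient
    max_log_rate: float = 50.0  # overflow guard on log lambda


def _nll_grad_raw(beta, X, y, delta, max_eta=50.0):
    eta = X @ beta
    mu = delta * np.exp(np.minimum(eta, max_eta))  # expected counts per bin
    nll = float(mu.sum() - y @ eta - y.sum() * np.log(delta))
    grad = X.T @ (mu - y)
    return nll, grad, mu


def nll_and_gradient(
    model: KernelModel, rs: RegressorSet, counts: Sequence[np.ndarray]
) -> Tuple[float, np.ndarray]:
    """Poisson NLL (log r! dropped) and its analytic gradient with respect to
    the intercept and every kernel lag, in the coefficient-vector layout."""
    y = rs.flatten_counts(counts)
    X = rs.matrix()
    if np.any(~np.isfinite(X.data)):
        raise ValueError("regressors contain non-finite values")
    nll, grad, _ = _nll_grad_raw(model.coef_vector(rs), X, y, rs.delta_s)
    return nll, grad


def fit_kernels(
    counts: Sequence[np.ndarray],
    rs: RegressorSet,
    fit_config: Optional[FitConfig] = None,
    init: Optional[KernelModel] = None,
    overrides: Optional[Dict[str, np.ndarray]] = None,
) -> KernelModel:
    """Maximum-likelihood kernels by damped Newton iterations.

    Initialization is all-zero kernels with the intercept at the log mean
    rate (or ``init``, e.g. to warm-start a shuffle refit; the objective is
    convex, so the optimum does not depend on the start). Deterministic.
    """
    cfg = fit_config or FitConfig()
    y = rs.flatten_counts(counts)
    if y.sum() == 0:
        raise DegenerateDataError("no spikes at all: the log-rate is unbounded below")
    X = rs.matrix(overrides)
    delta = rs.delta_s

    if init is not None:
        beta = init.coef_vector(rs).copy()
    else:
        beta = np.zeros(rs.n_cols)
        beta[0] = np.log(y.mean() / delta)

    nll, grad, mu = _nll_grad_raw(beta, X, y, delta, cfg.max_log_rate)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < cfg.tol_grad:
            converged = True
            it -= 1
            break
        # Newton direction from the exact Hessian X' diag(mu) X
        Xw = X.copy()
        Xw.data = Xw.data * np.repeat(mu, np.diff(X.indptr))
        H = (X.T @ Xw).toarray()
        step = _solve_spd(H, grad)
        t = 1.0
        while True:
            cand = beta - t * step
            new_nll, new_grad, new_mu = _nll_grad_raw(cand, X, y, delta, cfg.max_log_rate)
            if np.isfinite(new_nll) and new_nll <= nll + 1e-12:
                break
            t *= 0.5
            if t < 1e-12:
                cand, new_nll, new_grad, new_mu = beta, nll, grad, mu
                break
        rel_change = abs(nll - new_nll) / max(1.0, abs(new_nll))
        beta, nll, grad, mu = cand, new_nll, new_grad, new_mu
        if rel_change < cfg.tol_nll:
            converged = True
            break
    else:
        warnings.warn("kernel fit did not converge; returning partial result")

    return KernelModel.from_vector(beta, rs, nll, converged, it)


def _solve_spd(H, g):
    """Cholesky solve with Levenberg damping on numerically singular Hessians
    (e.g. lags never reached before the go cue carry no data)."""
    damp = 0.0
    scale = max(np.trace(H) / H.shape[0], 1e-12)
    for _ in range(12):
        try:
            c = cho_factor(H + damp * scale * np.eye(H.shape[0]), lower=True)
            return cho_solve(c, g)
        except np.linalg.LinAlgError:
            damp = 1e-10 if damp == 0.0 else damp * 100
    return np.linalg.lstsq(H, g, rcond=None)[0]


def predict_rate(model: KernelModel, rs: RegressorSet) -> List[np.ndarray]:
    """Model-implied rate lambda_t (spikes/s) per trial."""
    eta = rs.matrix() @ model.coef_vector(rs)
    return rs.split_per_trial(np.exp(eta))


def intercept_only_nll(counts: Sequence[np.ndarray], rs: RegressorSet,
                       mean_count: Optional[float] = None) -> float:
    """NLL of the homogeneous-rate model (closed form MLE unless a training
    mean is supplied)."""
    y = rs.flatten_counts(counts)
    m = y.mean() if mean_count is None else mean_count
    if m <= 0:
        raise DegenerateDataError("zero mean count")
    return float(len(y) * m - y.sum() * np.log(m))


def crossvalidate(
    counts: Sequence[np.ndarray],
    rs: RegressorSet,
    k_folds: int = 5,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
) -> dict:
    """Trial-level k-fold cross-validation with a seeded shuffle.

    Returns per-fold train/test NLL for the full model and for the
    intercept-only reference, plus their means.
    """
    if rs.n_trials < k_folds:
        raise ValueError(f"need at least {k_folds} trials for {k_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(rs.n_trials)
    folds = np.array_split(order, k_folds)
    out = {"folds": [], "fold_assignment": [np.sort(f).tolist() for f in folds]}
    counts = list(counts)
    for f in folds:
        test_idx = np.sort(f)
        train_idx = np.sort(np.setdiff1d(order, f))
        rs_tr, rs_te = rs.subset(train_idx), rs.subset(test_idx)
        c_tr = [counts[i] for i in train_idx]
        c_te = [counts[i] for i in test_idx]
        m = fit_kernels(c_tr, rs_tr, fit_config)
        test_nll, _ = nll_and_gradient(m, rs_te, c_te)
        mean_tr = rs_tr.flatten_counts(c_tr).mean()
        out["folds"].append(
            {
                "train_nll": m.nll,
                "test_nll": float(test_nll),
                "intercept_only_test_nll": intercept_only_nll(c_te, rs_te, mean_tr),
                "n_train": len(train_idx),
                "n_test": len(test_idx),
            }
        )
    out["mean_test_nll"] = float(np.mean([f["test_nll"] for f in out["folds"]]))
    out["mean_intercept_only_test_nll"] = float(
        np.mean([f["intercept_only_test_nll"] for f in out["folds"]])
    )
    return out
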