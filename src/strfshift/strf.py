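"""Ensemble STRF encoding models: ridge regression with jackknife CV.

The eSTRF is a causal linear map from the auditory spectrogram to HFB
amplitude,

    r_hat(t) = sum_tau sum_p g(tau, p) S(t - tau, p),

with lags tau in [0, 400] ms (21 lags on the 50 Hz grid).  Coefficients
are estimated by ridge regression; trials are repeatedly split
leave-one-out (jackknife), the held-out R^2 selects the ridge penalty,
and a single penalty (the mode over electrodes) is then fixed for all
refits.  Per-fold coefficient tensors give both the final gain (their
mean) and a t-value map (mean/std across folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "STRFFit",
    "DEFAULT_LAGS_S",
    "DEFAULT_RIDGE_GRID",
    "build_lagged_design",
    "fit_ridge",
    "fit_strf_jackknife",
    "fit_strf_jackknife_multi",
    "fit_strf_conditions_global",
    "select_global_ridge",
    "predict_hfb",
    "score_r2",
    "select_strf_responsive",
    "truth_on_standardized_scale",
]

#: 0-400 ms inclusive at 20 ms steps (the 50 Hz lag grid)
DEFAULT_LAGS_S = np.round(np.arange(21) * 0.02, 10)

#: log-spaced ridge penalties, 1e-2 .. 1e6
DEFAULT_RIDGE_GRID = np.logspace(-2, 6, 17)


@dataclass
class STRFFit:
    """Fitted eSTRF for one electrode.

    ``gain`` (n_lags x n_bands) is the mean of the per-fold coefficient
    tensors ``fold_gains``; ``tmap`` is mean/std across folds; ``ridge``
    the penalty the folds were refit at; ``fold_r2`` the held-out
    coefficient of determination per fold at that penalty and
    ``ci_lower_r2`` its 0.5th percentile (the lower bound of a
    two-sided 99% interval).

    Coefficients live on the standardized scale the model is fit on
    (z-scored stimulus features and response).  ``gain_raw`` is the same
    filter unstandardized back to raw stimulus/response units (each
    fold's coefficients divided by the training feature stds and
    multiplied by the training response std), the scale on which a
    generative ground-truth filter is directly comparable.
    """

    gain: np.ndarray
    fold_gains: np.ndarray
    tmap: np.ndarray
    ridge: float
    fold_r2: np.ndarray
    ci_lower_r2: float
    lags_s: np.ndarray = field(default_factory=lambda: DEFAULT_LAGS_S.copy())
    fold_argmax_ridge: np.ndarray | None = None
    gain_raw: np.ndarray | None = None

    @property
    def n_folds(self) -> int:
        return self.fold_gains.shape[0]


def lag_samples(lags_s: np.ndarray, rate: float) -> np.ndarray:
    """Convert a lag grid in seconds to integer sample lags.

    Raises ``ValueError`` if any lag is not a multiple of the sample
    period.
    """
    raw = np.asarray(lags_s, dtype=float) * rate
    lags = np.round(raw).astype(int)
    if np.any(np.abs(raw - lags) > 1e-6):
        raise ValueError("lag grid is not a multiple of the sample period")
    return lags


def build_lagged_design(
    S: np.ndarray,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    rate: float = 50.0,
) -> np.ndarray:
    """Time-lagged design matrix for one trial.

    Rows are time points, columns are (lag, band) pairs in lag-major
    order: column ``i * n_bands + p`` holds ``S(t - lags[i], p)``.
    Stimulus history before the start of the trial is zero-padded, so
    trial boundaries are never mixed (each trial builds its own design).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("S must be time x bands")
    lags = lag_samples(lags_s, rate)
    T, P = S.shape
    X = np.zeros((T, lags.size * P))
    for i, lag in enumerate(lags):
        if lag == 0:
            X[:, i * P : (i + 1) * P] = S
        elif lag < T:
            X[lag:, i * P : (i + 1) * P] = S[:-lag]
    return X


def fit_ridge(X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Ridge-regression coefficients, no intercept.

    Minimizes ``||y - Xw||^2 + ridge * ||w||^2`` via the SVD of X
    (numerically stable for any conditioning).  Inputs are expected to
    be standardized (zero mean) so no intercept is needed.
    """
    if ridge < 0:
        raise ValueError("ridge penalty must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    U, s, Vt = linalg.svd(X, full_matrices=False)
    tol = np.finfo(float).eps * max(X.shape) * (s[0] if s.size else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s > tol, s / (s**2 + ridge), 0.0)
    Uty = U.T @ y
    if y.ndim == 1:
        return Vt.T @ (d * Uty)
    return Vt.T @ (d[:, None] * Uty)


def score_r2(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    ``SS_tot`` is taken about the mean of ``actual``.  Cross-validated
    values can be negative when the prediction is worse than the mean.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = np.sum((actual - predicted) ** 2)
    ss_tot = np.sum((actual - actual.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def select_global_ridge(argmax_lambdas: np.ndarray) -> float:
    """Mode of the selected ridge penalties; ties go to the larger value
    (more regularization)."""
    lams = np.asarray(argmax_lambdas, dtype=float).ravel()
    if lams.size == 0:
        raise ValueError("no ridge selections to aggregate")
    vals, counts = np.unique(lams, return_counts=True)
    return float(vals[counts == counts.max()].max())


def select_strf_responsive(fit: STRFFit) -> bool:
    """True iff the 99% lower bound of held-out R^2 exceeds zero."""
    return bool(fit.ci_lower_r2 > 0)


def truth_on_standardized_scale(
    g_true: np.ndarray,
    stims: list[np.ndarray],
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    rate: float = 50.0,
) -> np.ndarray:
    """Map a generative (raw-scale) filter into the standardized
    coordinates a fit lives in.

    Fitted coefficients are per-feature rescaled by the stimulus feature
    stds (z-scoring the design multiplies the true coefficients
    elementwise by those stds, up to the scalar response std).  For
    parameter-recovery comparisons against ``STRFFit.gain`` the truth
    must be mapped the same way; ``STRFFit.gain_raw`` can instead be
    compared against the truth directly.
    """
    X = np.vstack([build_lagged_design(S, lags_s, rate) for S in stims])
    return np.asarray(g_true, dtype=float) * _safe_std(X).reshape(g_true.shape)


def _standardize(A: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (A - mean) / std


def _safe_std(A: np.ndarray, axis=0) -> np.ndarray:
    s = A.std(axis=axis)
    return np.where(s > 0, s, 1.0)


class _FoldSolver:
    """Eigendecomposition of one training fold's Gram matrix.

    Solving through ``X'X = V diag(e) V'`` lets every ridge penalty and
    every electrode share a single O(D^3) factorization per fold.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.evals, self.V = linalg.eigh(X.T @ X)
        self.evals = np.maximum(self.evals, 0.0)
        self.VtXtY = self.V.T @ (X.T @ Y)

    def coef(self, ridge: float | np.ndarray) -> np.ndarray:
        """Coefficients (D x E); ``ridge`` scalar or per-electrode."""
        ridge = np.atleast_1d(np.asarray(ridge, dtype=float))
        if ridge.size == 1:
            return self.V @ (self.VtXtY / (self.evals[:, None] + ridge[0]))
        return self.V @ (self.VtXtY / (self.evals[:, None] + ridge[None, :]))


def _jackknife_search(
    stims: list[np.ndarray],
    responses: list[np.ndarray],
    ridge_grid: np.ndarray,
    lags_s: np.ndarray,
    rate: float,
):
    """One jackknife pass: per-fold solvers plus the ridge-grid search.

    Returns ``(fold_meta, argmax_lam, shapes)`` where ``fold_meta`` holds
    the per-fold eigendecomposition and standardized held-out data, so
    final coefficients at any penalty can be produced without refitting.
    """
    n_trials = len(stims)
    if n_trials < 2:
        raise ValueError("jackknife needs at least 2 trials")
    if len(responses) != n_trials:
        raise ValueError("stims and responses must have one entry per trial")
    ridge_grid = np.asarray(ridge_grid, dtype=float)
    P = stims[0].shape[1]
    designs = [build_lagged_design(S, lags_s, rate) for S in stims]
    Ys = [np.atleast_2d(np.asarray(r, float).T).T for r in responses]
    E = Ys[0].shape[1]
    D = designs[0].shape[1]

    argmax_lam = np.empty((n_trials, E))
    fold_meta = []
    for k in range(n_trials):
        Xtr = np.vstack([designs[i] for i in range(n_trials) if i != k])
        Ytr = np.vstack([Ys[i] for i in range(n_trials) if i != k])
        if Xtr.shape[0] < 2 * D / 10:
            warnings.warn(
                f"fold {k}: only {Xtr.shape[0]} training samples for {D} "
                "parameters",
                RuntimeWarning,
            )
        xm, xs = Xtr.mean(axis=0), _safe_std(Xtr)
        ym, ys = Ytr.mean(axis=0), _safe_std(Ytr)
        Xtr = _standardize(Xtr, xm, xs)
        Ytr = _standardize(Ytr, ym, ys)
        Xte = _standardize(designs[k], xm, xs)
        Yte = _standardize(Ys[k], ym, ys)
        solver = _FoldSolver(Xtr, Ytr)
        ss_tot = np.sum((Yte - Yte.mean(axis=0)) ** 2, axis=0)
        r2 = np.empty((ridge_grid.size, E))
        for j, lam in enumerate(ridge_grid):
            pred = Xte @ solver.coef(lam)
            r2[j] = 1.0 - np.sum((Yte - pred) ** 2, axis=0) / ss_tot
        argmax_lam[k] = ridge_grid[np.argmax(r2, axis=0)]
        fold_meta.append((solver, Xte, Yte, ss_tot, xs, ys))
    return fold_meta, argmax_lam, (n_trials, D, E, P)


def _finalize_fits(
    fold_meta,
    argmax_lam: np.ndarray,
    shapes,
    final_lam: np.ndarray,
    lags_s: np.ndarray,
) -> list[STRFFit]:
    """Per-fold coefficients and scores at the fixed penalties."""
    n_trials, D, E, P = shapes
    fold_gains = np.empty((n_trials, D, E))
    fold_gains_raw = np.empty((n_trials, D, E))
    fold_r2 = np.empty((n_trials, E))
    for k, (solver, Xte, Yte, ss_tot, xs, ys) in enumerate(fold_meta):
        W = solver.coef(final_lam if np.unique(final_lam).size > 1 else final_lam[0])
        fold_gains[k] = W
        fold_gains_raw[k] = W / xs[:, None] * ys[None, :]
        fold_r2[k] = 1.0 - np.sum((Yte - Xte @ W) ** 2, axis=0) / ss_tot

    fits = []
    n_lags = len(lags_s)
    for e in range(E):
        fg = fold_gains[:, :, e].reshape(n_trials, n_lags, P)
        mean = fg.mean(axis=0)
        std = fg.std(axis=0, ddof=1)
        tmap = np.where(std > 0, mean / np.where(std > 0, std, 1.0), 0.0)
        fits.append(
            STRFFit(
                gain=mean,
                fold_gains=fg,
                tmap=tmap,
                ridge=float(final_lam[e]),
                fold_r2=fold_r2[:, e],
                ci_lower_r2=float(np.percentile(fold_r2[:, e], 0.5)),
                lags_s=np.asarray(lags_s, dtype=float),
                fold_argmax_ridge=argmax_lam[:, e],
                gain_raw=fold_gains_raw[:, :, e].mean(axis=0).reshape(n_lags, P),
            )
        )
    return fits


def fit_strf_jackknife_multi(
    stims: list[np.ndarray],
    responses: list[np.ndarray],
    ridge_grid: np.ndarray = DEFAULT_RIDGE_GRID,
    ridge: float | None = None,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    rate: float = 50.0,
) -> list[STRFFit]:
    """Jackknifed ridge eSTRFs for many electrodes sharing the stimuli.

    Parameters
    ----------
    stims : per-trial auditory spectrograms, each time x bands.
    responses : per-trial HFB, each time x electrodes (or 1-D).
    ridge_grid : penalties searched per fold (held-out R^2 argmax).
    ridge : if given, skip the search and refit every fold at this
        globally fixed penalty; otherwise each electrode uses the mode
        of its per-fold argmax penalties.

    Per electrode, per fold: standardize the training design and target
    (training statistics applied to the held-out trial), fit over the
    grid, record the held-out R^2 argmax; then refit at the fixed
    penalty to obtain per-fold coefficients, whose mean is the final
    gain and whose mean/std is the t-value map.
    """
    fold_meta, argmax_lam, shapes = _jackknife_search(
        stims, responses, ridge_grid, lags_s, rate
    )
    E = shapes[2]
    if ridge is not None:
        final_lam = np.full(E, float(ridge))
    else:
        final_lam = np.array(
            [select_global_ridge(argmax_lam[:, e]) for e in range(E)]
        )
    return _finalize_fits(fold_meta, argmax_lam, shapes, final_lam, lags_s)


def fit_strf_conditions_global(
    stims_by_cond: dict[str, list[np.ndarray]],
    responses_by_cond: dict[str, list[np.ndarray]],
    active: np.ndarray | None = None,
    ridge_grid: np.ndarray = DEFAULT_RIDGE_GRID,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    rate: float = 50.0,
) -> tuple[dict[str, list[STRFFit]], float]:
    """Condition-wise jackknife fits sharing a single global ridge.

    The penalty grid is searched once per condition; the per-fold argmax
    penalties of active electrodes, pooled across conditions, are
    aggregated by :func:`select_global_ridge`, and every condition's
    per-fold coefficients are then produced at that one penalty (so the
    coefficient prior is identical in all conditions).  Returns
    ``(fits_by_condition, global_ridge)``.
    """
    states = {}
    pooled = []
    for cond, stims in stims_by_cond.items():
        state = _jackknife_search(
            stims, responses_by_cond[cond], ridge_grid, lags_s, rate
        )
        states[cond] = state
        argmax = state[1]
        if active is not None:
            argmax = argmax[:, np.asarray(active, bool)]
        pooled.append(argmax.ravel())
    global_ridge = select_global_ridge(np.concatenate(pooled))
    fits = {}
    for cond, (fold_meta, argmax_lam, shapes) in states.items():
        final_lam = np.full(shapes[2], global_ridge)
        fits[cond] = _finalize_fits(fold_meta, argmax_lam, shapes, final_lam, lags_s)
    return fits, float(global_ridge)


def fit_strf_jackknife(
    trials: list[tuple[np.ndarray, np.ndarray]],
    ridge_grid: np.ndarray = DEFAULT_RIDGE_GRID,
    ridge: float | None = None,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    rate: float = 50.0,
) -> STRFFit:
    """Single-electrode convenience wrapper around the multi-target fit.

    ``trials`` is a list of (auditory spectrogram, HFB trace) pairs.
    """
    stims = [S for S, _ in trials]
    responses = [np.asarray(r, dtype=float).reshape(-1) for _, r in trials]
    return fit_strf_jackknife_multi(
        stims, responses, ridge_grid=ridge_grid, ridge=ridge, lags_s=lags_s, rate=rate
    )[0]


def predict_hfb(
    fit: STRFFit | np.ndarray,
    S: np.ndarray,
    rate: float = 50.0,
    lags_s: np.ndarray | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Predicted HFB trace: the gain tensor convolved with a spectrogram.

    With ``standardize=True`` (default) the lagged stimulus features are
    z-scored (with the prediction stimulus's own statistics), matching
    the per-feature standardization the model was fit with — z-scoring
    whole bands instead would misscale each lagged copy by 10-20% and
    wreck the cancellation between correlated coefficients.
    """
    if isinstance(fit, STRFFit):
        gain = fit.gain
        if lags_s is None:
            lags_s = fit.lags_s
    else:
        gain = np.asarray(fit, dtype=float)
        if lags_s is None:
            # bare tensor: rows are consecutive-sample lags at `rate`
            lags_s = np.arange(gain.shape[0]) / rate
    S = np.asarray(S, dtype=float)
    X = build_lagged_design(S, lags_s, rate)
    if standardize:
        X = _standardize(X, X.mean(axis=0), _safe_std(X))
    return X @ gain.ravel()
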