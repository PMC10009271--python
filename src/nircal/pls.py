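"""NIPALS PLS1 regression, cross-validated latent-variable selection and metrics.

The model is the classical bilinear decomposition

    X = T P' + E,   y = U q' + F,   U = T B  (B diagonal),

fitted by NIPALS on column-centred X and centred y.  For a single response
the NIPALS weight step needs no inner iteration: each weight vector is
``w = E'f / ||E'f||``.  Regression coefficients are folded back to the
original scale so that prediction is simply ``y_hat = b0 + X b``.

Two flavours of "R" are reported, because the literature prints both under
the same name: ``r_as_printed`` is the coefficient-of-determination style
quantity 1 - SSres/SStot (with SStot centred on the evaluated set's own
mean), and ``pearson_r`` is the plain Pearson correlation between observed
and predicted values.  Neither is silently substituted for the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, DegenerateDataError, SizeError

__all__ = [
    "PLSDecomposition",
    "PLSModel",
    "PredictionResult",
    "MetricsReport",
    "fit_pls",
    "predict",
    "loo_rmsecv",
    "kfold_rmsecv",
    "regression_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PLSDecomposition:
    scores_T: np.ndarray  # m x w
    scores_U: np.ndarray  # m x w
    x_loadings_P: np.ndarray  # w x n
    y_loadings_Q: np.ndarray  # w
    x_residual_E: np.ndarray  # m x n
    y_residual_F: np.ndarray  # m
    inner_B: np.ndarray  # w (diagonal of the inner relation U = T B)
    weights_W: np.ndarray  # n x w
    n_components_w: int


@dataclass(frozen=True)
class PLSModel:
    intercept_b0: float
    coefficients_b: np.ndarray  # length n, original (uncentred) scale
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    wavelength_indices: np.ndarray  # columns of the full grid this model uses
    decomposition: PLSDecomposition | None = None

    def to_dict(self) -> dict:
        return {
            "b0": float(self.intercept_b0),
            "b": self.coefficients_b.tolist(),
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "wavelength_indices": self.wavelength_indices.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            intercept_b0=float(d["b0"]),
            coefficients_b=np.asarray(d["b"], dtype=float),
            n_lv=int(d["n_lv"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            wavelength_indices=np.asarray(d["wavelength_indices"], dtype=int),
        )


@dataclass(frozen=True)
class PredictionResult:
    y_hat: np.ndarray
    residuals_e: np.ndarray | None = None  # y - y_hat when y was supplied


@dataclass(frozen=True)
class MetricsReport:
    mode: str  # "calibration" or "prediction"
    r_as_printed: float  # 1 - SSres/SStot
    pearson_r: float
    rmse: float  # mg/g; RMSEC(V) or RMSEP depending on context
    n_used: int
    y_mean: float


def _as_matrix(X) -> np.ndarray:
    if hasattr(X, "absorbance"):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _as_vector(y) -> np.ndarray:
    if hasattr(y, "values"):
        y = y.values
    return np.asarray(y, dtype=float).ravel()


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centred data; returns loadings and the coefficient path.

    ``b_path[:, a-1]`` are the centred-scale regression coefficients of the
    model truncated to ``a`` components.
    """
    m, n = Xc.shape
    E = Xc.copy()
    f = yc.copy()
    W = np.zeros((n, n_lv))
    P = np.zeros((n, n_lv))
    T = np.zeros((m, n_lv))
    U = np.zeros((m, n_lv))
    q = np.zeros(n_lv)
    actual = 0
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14 * max(1.0, np.linalg.norm(Xc)):
            break  # residual information exhausted
        w /= nw
        t = E @ w
        tt = t @ t
        if tt < 1e-300:
            break
        p = E.T @ t / tt
        qa = (f @ t) / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        U[:, a] = f  # PLS1 y-score: the current y residual
        E -= np.outer(t, p)
        f = f - qa * t
        actual = a + 1
    W, P, T, U, q = W[:, :actual], P[:, :actual], T[:, :actual], U[:, :actual], q[:actual]
    b_path = np.zeros((n, actual))
    for a in range(1, actual + 1):
        # b_a = W_a (P_a' W_a)^{-1} q_a ; the a x a solve is negligible
        M = P[:, :a].T @ W[:, :a]
        b_path[:, a - 1] = W[:, :a] @ np.linalg.solve(M, q[:a])
    return {
        "W": W,
        "P": P,
        "T": T,
        "U": U,
        "q": q,
        "E": E,
        "f": f,
        "b_path": b_path,
        "n_components": actual,
    }


def fit_pls(X, y, n_lv: int, wavelength_indices=None, keep_decomposition: bool = True) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    ``X`` may be a SpectraSet or an (m, n) array whose columns are the
    already-chosen wavelength subset; ``y`` a ReferenceSet or vector (mg/g).
    """
    X = _as_matrix(X)
    yv = _as_vector(y)
    m, n = X.shape
    if yv.size != m:
        raise DataError(f"X has {m} rows but y has {yv.size} entries")
    if np.std(yv) < 1e-12:
        raise DegenerateDataError("target y has no variance; nothing to regress")
    if n_lv < 1:
        raise SizeError("n_lv must be >= 1")
    if n_lv > min(m - 1, n):
        raise SizeError(f"n_lv={n_lv} exceeds min(m-1, n)={min(m - 1, n)}")
    x_mean = X.mean(axis=0)
    y_mean = float(yv.mean())
    fit = _nipals_path(X - x_mean, yv - y_mean, n_lv)
    w_used = fit["n_components"]
    b = fit["b_path"][:, w_used - 1]
    b0 = y_mean - float(x_mean @ b)
    wl_idx = (
        np.arange(n) if wavelength_indices is None else np.asarray(wavelength_indices, dtype=int)
    )
    decomposition = None
    if keep_decomposition:
        decomposition = PLSDecomposition(
            scores_T=fit["T"],
            scores_U=fit["U"],
            x_loadings_P=fit["P"].T,
            y_loadings_Q=fit["q"],
            x_residual_E=fit["E"],
            y_residual_F=fit["f"],
            inner_B=fit["q"].copy(),  # PLS1 inner coefficients coincide with q
            weights_W=fit["W"],
            n_components_w=w_used,
        )
    return PLSModel(
        intercept_b0=b0,
        coefficients_b=b,
        n_lv=w_used,
        x_mean=x_mean,
        y_mean=y_mean,
        wavelength_indices=wl_idx,
        decomposition=decomposition,
    )


def predict(model: PLSModel, X, y=None) -> PredictionResult:
    """Predict lignin content: ``y_hat = b0 + X b``."""
    X = _as_matrix(X)
    if X.shape[1] != model.coefficients_b.size:
        raise DataError(
            f"X has {X.shape[1]} columns, model expects {model.coefficients_b.size}"
        )
    y_hat = model.intercept_b0 + X @ model.coefficients_b
    residuals = None if y is None else _as_vector(y) - y_hat
    return PredictionResult(y_hat=y_hat, residuals_e=residuals)


def _coef_paths_cv(X, yv, max_lv, test_folds):
    """Shared CV engine: per fold fit a coefficient path on the training part
    and predict the held-out part for every component count."""
    m = X.shape[0]
    preds = np.full((m, max_lv), np.nan)
    for test_idx in test_folds:
        train_mask = np.ones(m, dtype=bool)
        train_mask[test_idx] = False
        Xt, yt = X[train_mask], yv[train_mask]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        cap = min(max_lv, Xt.shape[0] - 1, Xt.shape[1])
        fit = _nipals_path(Xt - x_mean, yt - y_mean, cap)
        bp = fit["b_path"]
        got = fit["n_components"]
        Xc_test = X[test_idx] - x_mean
        p = y_mean + Xc_test @ bp  # (n_test, got)
        preds[np.ix_(test_idx, range(got))] = p
        if got < max_lv:  # rank exhausted: later LV counts equal the last one
            preds[np.ix_(test_idx, range(got, max_lv))] = p[:, [-1]]
    return preds


def loo_rmsecv(X, y, max_lv: int):
    """Leave-one-out RMSECV for 1..max_lv components.

    Returns ``(rmsecv_per_lv, selected_lv)`` with the argmin broken toward
    the smaller component count.  ``max_lv`` beyond min(m-2, n) is capped
    with a logged warning rather than an error.
    """
    X = _as_matrix(X)
    yv = _as_vector(y)
    m, n = X.shape
    cap = min(m - 2, n)
    if max_lv > cap:
        logger.warning("max_lv=%d capped to %d (m=%d, n=%d)", max_lv, cap, m, n)
        max_lv = cap
    if max_lv < 1:
        raise SizeError("not enough samples for leave-one-out cross-validation")
    folds = [np.array([i]) for i in range(m)]
    preds = _coef_paths_cv(X, yv, max_lv, folds)
    rmsecv = np.sqrt(np.mean((yv[:, None] - preds) ** 2, axis=0))
    return rmsecv, int(np.argmin(rmsecv)) + 1


def kfold_rmsecv(X, y, max_lv: int, n_folds: int = 5):
    """Venetian-blind k-fold RMSECV per component count (deterministic folds).

    Sample i goes to fold ``i % n_folds``; no randomness, so repeated calls
    agree exactly.  Returns ``(rmsecv_per_lv, selected_lv)`` like
    :func:`loo_rmsecv`.
    """
    X = _as_matrix(X)
    yv = _as_vector(y)
    m, n = X.shape
    n_folds = min(n_folds, m)
    folds = [np.arange(m)[np.arange(m) % n_folds == k] for k in range(n_folds)]
    folds = [f for f in folds if f.size]
    cap = min(max_lv, m - int(max(f.size for f in folds)) - 1, n)
    if cap < 1:
        raise SizeError("not enough samples for k-fold cross-validation")
    preds = _coef_paths_cv(X, yv, cap, folds)
    rmsecv = np.sqrt(np.mean((yv[:, None] - preds) ** 2, axis=0))
    return rmsecv, int(np.argmin(rmsecv)) + 1


def regression_metrics(y_actual, y_pred, mode: str = "prediction") -> MetricsReport:
    """Calibration/prediction metrics: as-printed R, Pearson r and RMSE.

    ``r_as_printed`` is 1 - sum((y - y_hat)^2) / sum((y - mean(y))^2) with
    the mean taken over the evaluated set itself; RMSE is the plain root
    mean square error in mg/g.
    """
    ya = _as_vector(y_actual)
    yp = _as_vector(y_pred)
    if ya.size != yp.size:
        raise DataError("y_actual and y_pred lengths differ")
    if ya.size < 2:
        raise SizeError("need at least 2 samples for metrics")
    sstot = float(np.sum((ya - ya.mean()) ** 2))
    if sstot < 1e-24:
        raise DegenerateDataError("constant y_actual: R denominator is zero")
    ssres = float(np.sum((ya - yp) ** 2))
    rmse = float(np.sqrt(ssres / ya.size))
    if np.std(yp) < 1e-15:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(ya, yp)[0, 1])
    return MetricsReport(
        mode=mode,
        r_as_printed=1.0 - ssres / sstot,
        pearson_r=pearson,
        rmse=rmse,
        n_used=int(ya.size),
        y_mean=float(ya.mean()),
    )
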