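"""Correlation-constrained least-squares model updating (SS-FPME).

A calibration model built on one batch of samples degrades on later batches
(instrument drift, new interferents, seasonal sample changes).  Given a
supervising coefficient vector ``bm`` (from the master model, or from the
previously updated model) and a small labelled *update set* (Xs, y) from the
new batch, the update solves

    min_{b0s, bs}  || y - b0s - Xs bs ||^2
    s.t.           corr(bs, bm) >= rth

i.e. an ordinary least-squares refit whose coefficient vector is tethered to
the supervisor by a Pearson-correlation constraint.  The constraint (and
the warm start at ``bs = bm``) is what keeps the update from over-fitting
the typically tiny, under-determined update set: the optimizer descends the
residual while staying in the supervisor's neighbourhood.

Two schemes chain the updates across batches: *independent* updating always
supervises with the master model; *sequential* updating supervises batch i
with the coefficients produced for batch i-1.

The solver is scipy's SLSQP (sequential quadratic programming) with
analytic gradients for both the objective and the constraint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import ConfigError, DataError, DegenerateDataError, FeasibilityError
from .pls import MetricsReport, PLSModel, regression_metrics

__all__ = ["UpdateProblem", "UpdatedModel", "BatchTransferResult", "ssfpme_update", "run_update_scheme"]

logger = logging.getLogger(__name__)

_CONSTRAINT_SLACK = 1e-8


@dataclass(frozen=True)
class UpdateProblem:
    """One constrained update: supervisor coefficients + labelled update set.

    ``rth`` in [-1, 1): the Pearson-correlation floor between the updated and
    the supervising coefficient vectors (the intercept is unconstrained).
    ``init_b`` defaults to ``bm`` itself, which is always feasible; the
    intercept is warm-started at ``init_b0`` (the supervisor's intercept) or,
    if absent, at the value optimal for ``init_b``.
    """

    supervisor_bm: np.ndarray  # length p
    update_X: np.ndarray  # k x p
    update_y: np.ndarray  # length k, mg/g
    rth: float = 0.95
    init_b: np.ndarray | None = None
    init_b0: float | None = None

    def __post_init__(self):
        bm = np.asarray(self.supervisor_bm, dtype=float).ravel()
        X = np.asarray(self.update_X, dtype=float)
        y = np.asarray(self.update_y, dtype=float).ravel()
        object.__setattr__(self, "supervisor_bm", bm)
        object.__setattr__(self, "update_X", X)
        object.__setattr__(self, "update_y", y)
        if self.init_b is not None:
            object.__setattr__(self, "init_b", np.asarray(self.init_b, dtype=float).ravel())
        p = bm.size
        if p < 3:
            raise DataError(
                "need at least 3 coefficients: Pearson correlation between "
                "coefficient vectors is degenerate below that"
            )
        if np.std(bm) < 1e-14:
            raise DegenerateDataError("supervisor coefficients are constant; corr undefined")
        if X.ndim != 2 or X.shape[1] != p:
            raise DataError(f"update_X must be k x {p}")
        if X.shape[0] < 2 or y.size != X.shape[0]:
            raise DataError("update set needs k >= 2 aligned samples")
        if not -1.0 <= self.rth < 1.0:
            raise ConfigError(f"rth must lie in [-1, 1), got {self.rth}")
        if self.init_b is not None and self.init_b.size != p:
            raise DataError("init_b has the wrong length")


@dataclass(frozen=True)
class UpdatedModel:
    intercept_b0s: float
    coefficients_bs: np.ndarray
    constraint_value: float  # corr(bs, bm)
    objective: float  # squared residual norm on the update set
    converged: bool
    iterations: int
    rth: float
    supervisor_bm: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_b0s + X @ self.coefficients_bs

    def to_dict(self) -> dict:
        return {
            "b0": float(self.intercept_b0s),
            "b": self.coefficients_bs.tolist(),
            "rth": float(self.rth),
            "constraint_value": float(self.constraint_value),
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }


def coefficient_correlation(b1: np.ndarray, b2: np.ndarray) -> float:
    """Pearson correlation between two coefficient vectors."""
    b1 = np.asarray(b1, dtype=float).ravel()
    b2 = np.asarray(b2, dtype=float).ravel()
    u = b1 - b1.mean()
    v = b2 - b2.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        raise DegenerateDataError("constant coefficient vector; correlation undefined")
    return float(u @ v / (nu * nv))


def _cone_solve(X, y, vhat, rth, *, outer_iters: int = 200):
    """Exact minimiser of ||y - b0 - Xb||^2 over the cone corr(b, bm) >= rth.

    Valid for 0 <= rth < 1, where the feasible set is convex.  Decompose
    ``b = c*1 + u1*vhat + W w`` (``vhat`` the unit centred supervisor
    direction, ``W`` an orthonormal basis of the centred subspace orthogonal
    to ``vhat``).  The constraint becomes the second-order cone
    ``||w|| <= tan(theta) * u1`` with ``theta = arccos(rth)``.  For fixed
    ``u1`` the inner problem is a trust-region subproblem solved exactly via
    the SVD secular equation; the outer value function is convex in ``u1``,
    so golden-section search finds the global optimum.

    Returns ``(b0, b, objective, n_evals)``.
    """
    k, p = X.shape
    ones_p = np.ones(p)
    # orthonormal basis of the centred subspace orthogonal to vhat
    basis = np.column_stack([ones_p / np.sqrt(p), vhat, np.eye(p)])
    Q_full, _ = np.linalg.qr(basis)
    W = Q_full[:, 2:p]

    F = np.column_stack([np.ones(k), X @ ones_p])  # free part: intercept + constant shift
    QF, _ = np.linalg.qr(F)

    def perp(v):
        return v - QF @ (QF.T @ v)

    Py = perp(y)
    Pxv = perp(X @ vhat)
    G = np.column_stack([perp(X @ W[:, j]) for j in range(W.shape[1])])
    U, S, Vt = np.linalg.svd(G, full_matrices=False)
    rank_mask = S > S[0] * 1e-12 if S.size and S[0] > 0 else np.zeros(S.size, bool)
    d0 = U.T @ Py
    d1 = U.T @ Pxv
    yy, yv, vv = float(Py @ Py), float(Py @ Pxv), float(Pxv @ Pxv)
    tan_theta = np.inf if rth <= 0 else np.sqrt(max(1.0 - rth * rth, 0.0)) / rth

    def inner(u1):
        """Exact trust-region subproblem at height u1; returns (phi, q)."""
        d = d0 - u1 * d1
        h_sq = yy - 2.0 * u1 * yv + u1 * u1 * vv
        rho = tan_theta * u1
        q = np.zeros_like(d)
        if S.size:
            q[rank_mask] = d[rank_mask] / S[rank_mask]
            if np.isfinite(rho) and q @ q > rho * rho:
                # secular equation: ||q(mu)|| = rho with q_j = s_j d_j/(s_j^2+mu)
                sd = S * d
                lo, hi = 0.0, max(S[0] * np.linalg.norm(d) / max(rho, 1e-300), 1.0)
                while np.sum((sd / (S * S + hi)) ** 2) > rho * rho:
                    hi *= 4.0
                for _ in range(200):
                    mu = 0.5 * (lo + hi)
                    if np.sum((sd / (S * S + mu)) ** 2) > rho * rho:
                        lo = mu
                    else:
                        hi = mu
                    if hi - lo <= 1e-14 * max(hi, 1.0):
                        break
                q = sd / (S * S + 0.5 * (lo + hi))
        sq = S * q
        phi = h_sq - 2.0 * float(d @ sq) + float(sq @ sq)
        return phi, q

    # bracket the convex outer function, then golden-section search
    scale = max(np.linalg.norm(d0) / max(S[0], 1e-300) if S.size else 1.0, 1.0)
    hi = scale
    n_evals = 0
    while inner(hi)[0] <= inner(0.5 * hi)[0] and hi < 1e12 * scale:
        hi *= 2.0
        n_evals += 2
    lo = 0.0
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, f2 = inner(c1)[0], inner(c2)[0]
    for _ in range(outer_iters):
        if f1 <= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = inner(c1)[0]
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = inner(c2)[0]
        n_evals += 1
        if b - a <= 1e-12 * max(b, 1.0):
            break
    u1 = 0.5 * (a + b)
    # keep strictly off the cone apex: at u1 ~ 0 the correlation is a 0/0
    # ratio and roundoff can push it below rth; a tiny positive height costs
    # only O(u1) objective (the value function is continuous at 0)
    u1 = max(u1, 1e-7 * scale)
    _, q = inner(u1)
    w = Vt.T @ q
    if np.isfinite(tan_theta):
        w_cap = tan_theta * u1 * (1.0 - 1e-9)
        w_norm = np.linalg.norm(w)
        if w_norm > w_cap:
            w *= w_cap / w_norm
    u = u1 * vhat + W @ w
    free, *_ = np.linalg.lstsq(F, y - X @ u, rcond=None)
    b_vec = u + free[1] * ones_p
    r = y - free[0] - X @ b_vec
    return float(free[0]), b_vec, float(r @ r), n_evals


def ssfpme_update(
    problem: UpdateProblem,
    *,
    ftol: float = 1e-10,
    max_iter: int = 500,
) -> UpdatedModel:
    """Solve the correlation-constrained least-squares update.

    Route: (1) if the unconstrained least-squares solution already satisfies
    the correlation floor it is the global optimum and is returned directly;
    (2) otherwise an SQP solve (SLSQP, analytic gradients) starts from the
    supervisor ``bm`` — on under-determined update sets this lands on the
    zero-residual solution nearest the supervisor, which is exactly the
    behaviour that makes the update generalise; (3) for ``rth >= 0`` an exact
    second-order-cone solve of the binding case runs as arbiter, and the
    better feasible solution wins.

    Guarantees (enforced, not just hoped for): the returned objective never
    exceeds the objective at the feasible initializer, and the returned
    coefficients satisfy ``corr(bs, bm) >= rth - 1e-8``; otherwise the
    initializer is returned with ``converged=False`` and a warning.
    """
    bm = problem.supervisor_bm
    X = problem.update_X
    y = problem.update_y
    k, p = X.shape
    rth = problem.rth

    b_init = bm.copy() if problem.init_b is None else problem.init_b.copy()
    init_corr = coefficient_correlation(b_init, bm)
    if init_corr < rth - _CONSTRAINT_SLACK:
        raise FeasibilityError(
            f"starting point has corr(init_b, bm)={init_corr:.6f} < rth={rth}"
        )
    if problem.init_b0 is not None:
        b0_init = float(problem.init_b0)
    else:
        b0_init = float(np.mean(y - X @ b_init))

    bm_c = bm - bm.mean()
    vhat = bm_c / np.linalg.norm(bm_c)

    def objective(theta):
        r = y - theta[0] - X @ theta[1:]
        grad = np.empty(p + 1)
        grad[0] = -2.0 * r.sum()
        grad[1:] = -2.0 * (X.T @ r)
        return float(r @ r), grad

    def safe_corr(b):
        u = b - b.mean()
        nu = np.linalg.norm(u)
        return float(u @ vhat) / nu if nu > 1e-300 else -np.inf

    # homogeneous (degree-1) form of the correlation constraint: well scaled
    # for SQP, equivalent to corr(b, bm) >= rth away from constant b
    def constraint(theta):
        u = theta[1:] - theta[1:].mean()
        return float(u @ vhat) - rth * np.linalg.norm(u)

    def constraint_jac(theta):
        u = theta[1:] - theta[1:].mean()
        nu = np.linalg.norm(u) + 1e-300
        g_u = vhat - rth * u / nu
        jac = np.zeros(p + 1)
        jac[1:] = g_u - g_u.mean()  # chain rule through the centring projector
        return jac

    theta0 = np.concatenate([[b0_init], b_init])
    obj0 = objective(theta0)[0]

    # (1) unconstrained optimum, globally optimal when feasible
    A = np.column_stack([np.ones(k), X])
    ls, *_ = np.linalg.lstsq(A, y, rcond=None)
    ls_obj = objective(ls)[0]
    if rth <= -1.0 + 1e-12 or safe_corr(ls[1:]) >= rth - _CONSTRAINT_SLACK:
        obj, corr = ls_obj, safe_corr(ls[1:])
        bs, b0s, iterations, converged = ls[1:], float(ls[0]), 0, True
        if obj > obj0:  # numerically possible only in pathological rank cases
            bs, b0s, obj, corr, converged = b_init, b0_init, obj0, init_corr, False
        return UpdatedModel(
            intercept_b0s=b0s, coefficients_bs=bs, constraint_value=corr,
            objective=obj, converged=converged, iterations=iterations,
            rth=rth, supervisor_bm=bm.copy(),
        )

    # (2) SQP from the supervisor
    res = minimize(
        objective, theta0, jac=True, method="SLSQP",
        constraints=[{"type": "ineq", "fun": constraint, "jac": constraint_jac}],
        options={"maxiter": max_iter, "ftol": ftol},
    )
    cand_b0, cand_b = float(res.x[0]), res.x[1:]
    cand_obj = objective(res.x)[0]
    cand_corr = safe_corr(cand_b)
    feasible = cand_corr >= rth - _CONSTRAINT_SLACK
    iterations = int(res.nit)
    converged = bool(res.success) and feasible

    # (3) exact convex-cone solve as arbiter (rth >= 0 keeps the set convex)
    if rth >= 0.0:
        e_b0, e_b, e_obj, e_evals = _cone_solve(X, y, vhat, rth)
        e_corr = safe_corr(e_b)
        if e_corr >= rth - _CONSTRAINT_SLACK:
            if not feasible or e_obj < cand_obj * (1.0 - 1e-9) - 1e-12:
                cand_b0, cand_b, cand_obj, cand_corr = e_b0, e_b, e_obj, e_corr
                feasible, converged, iterations = True, True, e_evals
            elif cand_obj <= e_obj * (1.0 + 1e-9) + 1e-12:
                converged = feasible  # SQP iterate verified optimal by the arbiter

    bs, b0s, obj, corr = cand_b, cand_b0, cand_obj, cand_corr
    # never return something worse or infeasible relative to the initializer
    if obj > obj0 or not feasible:
        bs, b0s, obj, corr, converged = b_init, b0_init, obj0, init_corr, False
    if not converged:
        warnings.warn(
            "SS-FPME solver did not fully converge; returning the best feasible iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return UpdatedModel(
        intercept_b0s=b0s,
        coefficients_bs=bs,
        constraint_value=corr,
        objective=obj,
        converged=converged,
        iterations=iterations,
        rth=rth,
        supervisor_bm=bm.copy(),
    )


@dataclass(frozen=True)
class BatchTransferResult:
    """Per-batch outcome of a transfer scheme."""

    batch_name: str
    direct_metrics: MetricsReport  # master model applied unchanged
    updated_metrics: MetricsReport  # after the SS-FPME update
    updated_model: UpdatedModel


def run_update_scheme(
    master: PLSModel,
    batches,
    scheme: str = "sequential",
    rth: float = 0.95,
    solver_options: dict | None = None,
) -> list:
    """Apply SS-FPME updating over an ordered list of new batches.

    ``batches`` is a list of ``(name, update_X, update_y, test_X, test_y)``
    tuples (``name`` optional: 4-tuples are accepted), all on the master
    model's wavelength subset and preprocessing.

    ``scheme="independent"`` supervises every batch with the master's
    coefficients; ``scheme="sequential"`` supervises batch i with the
    coefficients produced for batch i-1.  For each batch the *direct*
    baseline applies the unmodified master model to the test set.
    """
    if scheme not in ("independent", "sequential"):
        raise ConfigError(f"unknown scheme {scheme!r}")
    batches = list(batches)
    if not batches:
        raise ConfigError("no batches to update on")
    solver_options = solver_options or {}
    p = master.coefficients_b.size

    results = []
    supervisor_b = master.coefficients_b
    supervisor_b0 = master.intercept_b0
    for i, entry in enumerate(batches):
        if len(entry) == 5:
            name, up_X, up_y, te_X, te_y = entry
        else:
            up_X, up_y, te_X, te_y = entry
            name = f"batch{i + 1}"
        up_X = np.asarray(up_X, dtype=float)
        te_X = np.asarray(te_X, dtype=float)
        if up_X.shape[1] != p or te_X.shape[1] != p:
            raise DataError(
                f"batch {name}: columns ({up_X.shape[1]}) do not match the "
                f"master model's wavelength subset ({p})"
            )
        direct_pred = master.intercept_b0 + te_X @ master.coefficients_b
        direct = regression_metrics(te_y, direct_pred, mode="prediction")

        problem = UpdateProblem(
            supervisor_bm=supervisor_b,
            update_X=up_X,
            update_y=up_y,
            rth=rth,
            init_b0=supervisor_b0,
        )
        updated = ssfpme_update(problem, **solver_options)
        upd_metrics = regression_metrics(te_y, updated.predict(te_X), mode="prediction")
        results.append(
            BatchTransferResult(
                batch_name=str(name),
                direct_metrics=direct,
                updated_metrics=upd_metrics,
                updated_model=updated,
            )
        )
        if scheme == "sequential":
            supervisor_b = updated.coefficients_bs
            supervisor_b0 = updated.intercept_b0s
    return results
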