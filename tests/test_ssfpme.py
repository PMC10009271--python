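import numpy as np
import pytest

from nircal.exceptions import ConfigError, DataError, DegenerateDataError, FeasibilityError
from nircal.pls import fit_pls
from nircal.ssfpme import (
    UpdateProblem,
    coefficient_correlation,
    run_update_scheme,
    ssfpme_update,
)


def lstsq_fit(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return coef, float(r @ r)


def direction_grid_oracle(bm, X, y, rth, n_grid=260):
    """Dense direction grid + polish for p=3, independent of the solver.

    Any coefficient vector is s*d with s >= 0 and d on the unit sphere; the
    constraint depends only on d, and for fixed d the optimum over
    (intercept, s) is a tiny least-squares problem.  The best grid cell is
    polished with Nelder-Mead over the sphere angles.
    """
    from scipy.optimize import minimize as nm

    bmc = bm - bm.mean()
    bmn = np.linalg.norm(bmc)

    def value(angles):
        th, ph = angles
        d = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        dc = d - d.mean()
        nd = np.linalg.norm(dc)
        if nd < 1e-12 or dc @ bmc / (nd * bmn) < rth:
            return np.inf
        A = np.column_stack([np.ones(len(y)), X @ d])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[1] < 0:  # negative scale flips the correlation sign
            coef[1] = 0.0
        r = y - A @ coef
        return float(r @ r)

    thetas = np.linspace(0, np.pi, n_grid)
    phis = np.linspace(0, 2 * np.pi, 2 * n_grid, endpoint=False)
    cells = []
    for th in thetas:
        for ph in phis:
            v = value((th, ph))
            if np.isfinite(v):
                cells.append((v, (th, ph)))
    cells.sort(key=lambda c: c[0])
    best = cells[0][0]
    for _, start in cells[:10]:  # polish the best grid cells
        res = nm(value, start, method="Nelder-Mead",
                 options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best


class TestValidation:
    def test_too_few_coefficients_rejected(self, rng):
        with pytest.raises(DataError):
            UpdateProblem(np.array([1.0, 2.0]), rng.normal(size=(4, 2)), rng.normal(size=4))

    def test_constant_supervisor_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            UpdateProblem(np.full(4, 2.0), rng.normal(size=(5, 4)), rng.normal(size=5))

    def test_bad_rth_rejected(self, rng):
        with pytest.raises(ConfigError):
            UpdateProblem(rng.normal(size=4), rng.normal(size=(5, 4)),
                          rng.normal(size=5), rth=1.0)

    def test_infeasible_start_rejected(self, rng):
        bm = np.array([1.0, 2.0, 3.0, 4.0])
        problem = UpdateProblem(
            bm, rng.normal(size=(6, 4)), rng.normal(size=6), rth=0.9,
            init_b=-bm,  # corr(-bm, bm) = -1
        )
        with pytest.raises(FeasibilityError):
            ssfpme_update(problem)


class TestSolver:
    def test_vacuous_constraint_matches_least_squares(self, rng):
        for _ in range(5):
            X = rng.normal(size=(20, 4))
            y = rng.normal(size=20)
            bm = rng.normal(size=4)
            up = ssfpme_update(UpdateProblem(bm, X, y, rth=-1.0))
            coef, obj = lstsq_fit(X, y)
            assert np.max(np.abs(up.coefficients_bs - coef[1:])) < 1e-6
            assert abs(up.intercept_b0s - coef[0]) < 1e-6
            assert abs(up.objective - obj) < 1e-8

    def test_noiseless_supervisor_is_global_minimum(self, rng):
        bm = rng.normal(size=6)
        X = rng.normal(size=(12, 6))
        y = 1.5 + X @ bm
        up = ssfpme_update(UpdateProblem(bm, X, y, rth=0.9, init_b0=1.5))
        assert up.objective < 1e-10
        assert np.max(np.abs(up.coefficients_bs - bm)) < 1e-6

    def test_three_coefficient_problems_match_grid_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 6:
            bm = rng.normal(size=3)
            X = rng.normal(size=(6, 3))
            y = X @ rng.normal(size=3) + rng.normal(size=6) * 0.5
            coef, _ = lstsq_fit(X, y)
            if coefficient_correlation(coef[1:], bm) >= 0.95:
                continue  # want the constraint to bind
            up = ssfpme_update(UpdateProblem(bm, X, y, rth=0.95))
            oracle = direction_grid_oracle(bm, X, y, 0.95)
            assert up.objective == pytest.approx(oracle, rel=1e-4, abs=1e-10)
            checked += 1

    def test_constraint_satisfied_and_no_worse_than_init(self, rng):
        for _ in range(10):
            p = int(rng.integers(3, 10))
            k = int(rng.integers(4, 25))
            bm = rng.normal(size=p)
            X = rng.normal(size=(k, p))
            y = X @ rng.normal(size=p) + rng.normal(size=k)
            rth = float(rng.uniform(0.0, 0.98))
            up = ssfpme_update(UpdateProblem(bm, X, y, rth=rth))
            assert up.constraint_value >= rth - 1e-8
            init_obj = float(np.sum((y - np.mean(y - X @ bm) - X @ bm) ** 2))
            assert up.objective <= init_obj + 1e-9

    def test_objective_monotone_in_rth(self, rng):
        for _ in range(5):
            bm = rng.normal(size=5)
            X = rng.normal(size=(12, 5))
            y = X @ rng.normal(size=5) + rng.normal(size=12) * 0.3
            objs = [
                ssfpme_update(UpdateProblem(bm, X, y, rth=r)).objective
                for r in (-1.0, 0.0, 0.4, 0.7, 0.9, 0.97)
            ]
            assert all(a <= b + 1e-7 for a, b in zip(objs, objs[1:]))


class TestUpdateScheme:
    @staticmethod
    def _make_batches(rng, n_batches, p=6, k=15):
        master_X = rng.normal(size=(30, p))
        master_y = master_X @ rng.normal(size=p) + rng.normal(size=30) * 0.1 + 78
        master = fit_pls(master_X, master_y, min(p, 5), keep_decomposition=False)
        batches = []
        for i in range(n_batches):
            X = rng.normal(size=(k, p))
            y = X @ rng.normal(size=p) * 0.5 + 78 + rng.normal(size=k) * 0.1
            Xt = rng.normal(size=(k, p))
            yt = Xt @ rng.normal(size=p) * 0.5 + 78 + rng.normal(size=k) * 0.1
            batches.append((f"b{i}", X, y, Xt, yt))
        return master, batches

    def test_single_batch_schemes_coincide(self, rng):
        master, batches = self._make_batches(rng, 1)
        ind = run_update_scheme(master, batches, scheme="independent", rth=0.8)
        seq = run_update_scheme(master, batches, scheme="sequential", rth=0.8)
        assert np.array_equal(
            ind[0].updated_model.coefficients_bs, seq[0].updated_model.coefficients_bs
        )
        assert ind[0].updated_model.intercept_b0s == seq[0].updated_model.intercept_b0s

    def test_sequential_chains_supervisors(self, rng):
        master, batches = self._make_batches(rng, 3)
        seq = run_update_scheme(master, batches, scheme="sequential", rth=0.8)
        # batch 3's supervisor is bit-comparable to batch 2's solution
        assert np.array_equal(
            seq[2].updated_model.supervisor_bm, seq[1].updated_model.coefficients_bs
        )
        ind = run_update_scheme(master, batches, scheme="independent", rth=0.8)
        for res in ind:
            assert np.array_equal(res.updated_model.supervisor_bm, master.coefficients_b)

    def test_direct_metrics_use_unmodified_master(self, rng):
        master, batches = self._make_batches(rng, 2)
        out = run_update_scheme(master, batches, scheme="sequential", rth=0.8)
        from nircal.pls import predict, regression_metrics

        for (name, _, _, Xt, yt), res in zip(batches, out):
            expect = regression_metrics(yt, predict(master, Xt).y_hat)
            assert res.direct_metrics.rmse == pytest.approx(expect.rmse)

    def test_empty_batch_list_rejected(self, rng):
        master, _ = self._make_batches(rng, 1)
        with pytest.raises(ConfigError):
            run_update_scheme(master, [], scheme="independent")

    def test_column_mismatch_rejected(self, rng):
        master, batches = self._make_batches(rng, 1)
        name, X, y, Xt, yt = batches[0]
        with pytest.raises(DataError):
            run_update_scheme(master, [(name, X[:, :4], y, Xt, yt)])
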