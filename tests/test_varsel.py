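import numpy as np
import pytest

from nircal.exceptions import ConfigError
from nircal.pls import loo_rmsecv
from nircal.synthdata import generate_batch, single_band_config
from nircal.varsel import (
    GAConfig,
    cars_edf,
    cars_select,
    ga_select,
    sipls_intervals,
    sipls_select,
    spa_select,
)


@pytest.fixture(scope="module")
def band_data():
    """Small dataset where only a 12-ish-column band carries lignin signal."""
    cfg = single_band_config()
    batch = generate_batch(cfg, "band", seed=3)
    info = batch.truth["informative_indices"]
    return batch.spectra.absorbance, batch.references.values, info


def in_band_fraction(selected, info, slop=2):
    ok = set()
    for i in info:
        ok.update(range(i - slop, i + slop + 1))
    return np.mean([i in ok for i in selected])


class TestGA:
    def test_single_wavelength_trivial(self, rng):
        X = rng.normal(size=(20, 1))
        y = 2.0 * X[:, 0] + rng.normal(size=20) * 0.1
        res = ga_select(X, y, seed=0)
        assert list(res.selected_indices) == [0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(population=0)

    def test_best_score_trace_non_increasing(self, band_data):
        X, y, _ = band_data
        cfg = GAConfig(population=16, generations=8, max_lv=6)
        res = ga_select(X, y, config=cfg, seed=1)
        assert all(a >= b - 1e-12 for a, b in zip(res.history, res.history[1:]))

    def test_deterministic_under_seed(self, band_data):
        X, y, _ = band_data
        cfg = GAConfig(population=12, generations=5, max_lv=5)
        a = ga_select(X, y, config=cfg, seed=7)
        b = ga_select(X, y, config=cfg, seed=7)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.score_rmsecv == b.score_rmsecv


class TestCARS:
    def test_edf_closed_form(self):
        # r_i = a e^{-k i} with r_1 = 1 and r_N = 2/n: n=100, N=100 -> 0.02
        r = cars_edf(100, 100)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(0.02)

    def test_deterministic_under_seed(self, band_data):
        X, y, _ = band_data
        a = cars_select(X, y, n_runs=30, seed=5)
        b = cars_select(X, y, n_runs=30, seed=5)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.history == b.history

    def test_selected_subset_not_worse_than_full(self, band_data):
        """Dropping uninformative columns should not hurt cross-validation."""
        X, y, _ = band_data
        wins = 0
        for seed in range(6):
            res = cars_select(X, y, n_runs=40, seed=seed)
            full, lv = loo_rmsecv(X, y, 10)
            wins += res.score_rmsecv <= full[lv - 1]
        assert wins >= 4


class TestSPA:
    def test_chain_of_one_returns_start(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        res = spa_select(X, y, k_min=1, k_max=1)
        assert res.selected_indices.size == 1

    def test_duplicate_column_never_follows_twin(self, rng):
        X = rng.normal(size=(12, 5))
        X[:, 3] = X[:, 1]  # exact duplicate
        y = rng.normal(size=12)
        res = spa_select(X, y, k_min=2, k_max=4)
        sel = set(res.selected_indices)
        assert not {1, 3} <= sel

    def test_orthogonal_columns_chain_by_norm(self):
        # orthogonal columns: projection removes nothing, so the chain from
        # column 0 picks the remaining columns in decreasing norm order
        Q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(5, 4)))
        norms = np.array([1.0, 4.0, 3.0, 2.0])
        X = Q * norms
        from nircal.varsel import _spa_chain

        assert _spa_chain(X, 0, 4) == [0, 1, 2, 3]

    def test_k_range_validated(self, rng):
        with pytest.raises(ConfigError):
            spa_select(rng.normal(size=(10, 4)), rng.normal(size=10), k_min=3, k_max=2)


class TestSiPLS:
    def test_interval_partition_arithmetic(self):
        parts = sipls_intervals(387, 20)
        sizes = [p.size for p in parts]
        assert sizes == [20] * 7 + [19] * 13
        assert sum(sizes) == 387
        assert np.array_equal(np.concatenate(parts), np.arange(387))

    def test_combo_size_validated(self, rng):
        with pytest.raises(ConfigError):
            sipls_select(rng.normal(size=(10, 40)), rng.normal(size=10),
                         n_intervals=20, combo_sizes=(25,))

    def test_winning_combination_contains_signal_interval(self, band_data):
        X, y, info = band_data
        parts = sipls_intervals(X.shape[1], 10)
        signal_intervals = {
            i for i, p in enumerate(parts) if np.intersect1d(p, info).size
        }
        res = sipls_select(X, y, n_intervals=10, combo_sizes=(2, 3), max_lv=8)
        chosen = {
            i for i, p in enumerate(parts)
            if np.intersect1d(p, res.selected_indices).size
        }
        assert chosen & signal_intervals


class TestConsistency:
    @pytest.mark.parametrize("method", ["ga", "cars", "spa", "sipls"])
    def test_score_reproducible_from_indices(self, band_data, method):
        X, y, _ = band_data
        if method == "ga":
            res = ga_select(X, y, config=GAConfig(population=12, generations=4, max_lv=6), seed=2)
            max_lv = 6
        elif method == "cars":
            res = cars_select(X, y, n_runs=25, seed=2)
            max_lv = 10
        elif method == "spa":
            res = spa_select(X, y, k_min=3, k_max=10)
            max_lv = min(20, res.selected_indices.size)
        else:
            res = sipls_select(X, y, n_intervals=10, combo_sizes=(2,), max_lv=8)
            max_lv = 8
        rmsecv, lv = loo_rmsecv(X[:, res.selected_indices], y, max_lv)
        assert res.score_rmsecv == pytest.approx(float(rmsecv[lv - 1]), abs=1e-10)
        assert res.n_lv == lv
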