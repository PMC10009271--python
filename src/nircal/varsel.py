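"""Effective-wavelength selection: GA, CARS, SPA and SiPLS.

All four methods return a :class:`SelectionResult` whose ``score_rmsecv``
is always recomputed by leave-one-out cross-validated PLS on the final
selected columns, whatever cheaper cross-validation the search itself used
internally — so the reported score is reproducible from the indices alone.

* **GA** evolves binary wavelength masks; fitness is the (negated)
  cross-validated RMSECV of a PLS model on the masked columns.
* **CARS** (competitive adaptive reweighted sampling) runs Monte Carlo
  PLS fits, each time keeping a fraction of wavelengths given by an
  exponentially decreasing function (EDF) of the run number, then
  resampling survivors with probability proportional to |coefficient|.
* **SPA** (successive projections algorithm) grows minimally collinear
  chains by repeated orthogonal projection, scoring each chain length by
  multiple linear regression on an internal validation split.
* **SiPLS** (synergy-interval PLS) partitions the grid into contiguous
  intervals and exhaustively scores every combination of 2-4 of them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, SizeError
from .pls import _as_matrix, _as_vector, kfold_rmsecv, loo_rmsecv
from .sampling import kennard_stone_indices

__all__ = [
    "SelectionResult",
    "GAConfig",
    "ga_select",
    "cars_select",
    "cars_edf",
    "spa_select",
    "sipls_select",
    "sipls_intervals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected_indices: np.ndarray  # sorted, unique, into the trimmed grid
    selected_nm: np.ndarray | None
    score_rmsecv: float  # LOO RMSECV on the selected columns, mg/g
    n_lv: int  # the component count achieving score_rmsecv
    history: list  # per-iteration best score trace
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_indices": self.selected_indices.tolist(),
            "selected_nm": None if self.selected_nm is None else self.selected_nm.tolist(),
            "score_rmsecv": float(self.score_rmsecv),
            "n_lv": int(self.n_lv),
            "history": [float(h) for h in self.history],
            "seed": self.seed,
        }


def _finalize(method, X, y, indices, wavelengths, history, seed, max_lv):
    idx = np.unique(np.asarray(indices, dtype=int))
    if idx.size == 0:
        raise SizeError(f"{method}: empty selection")
    rmsecv, lv = loo_rmsecv(X[:, idx], y, max_lv)
    return SelectionResult(
        method=method,
        selected_indices=idx,
        selected_nm=None if wavelengths is None else wavelengths[idx],
        score_rmsecv=float(rmsecv[lv - 1]),
        n_lv=lv,
        history=list(history),
        seed=seed,
    )


def _subset_rmsecv(X, y, idx, max_lv, cv_folds):
    """min-over-LV k-fold RMSECV on a column subset (the search-time score)."""
    rmsecv, lv = kfold_rmsecv(X[:, idx], y, max_lv, n_folds=cv_folds)
    return float(rmsecv[lv - 1])


def _unpack(X, y):
    Xm = _as_matrix(X)
    wavelengths = np.asarray(X.wavelengths, dtype=float) if hasattr(X, "wavelengths") else None
    return Xm, _as_vector(y), wavelengths


# --------------------------------------------------------------------------
# genetic algorithm
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    population: int = 100
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    elitism: int = 2
    tournament_size: int = 3
    init_prob: float = 0.30  # expected fraction of wavelengths set in generation 0
    cv_folds: int = 5  # 0 means leave-one-out fitness
    max_lv: int = 20
    max_selected: int | None = None  # optional cap on chromosome cardinality

    def __post_init__(self):
        if self.population < 1 or self.generations < 1:
            raise ConfigError("population and generations must be >= 1")
        if self.elitism >= self.population:
            raise ConfigError("elitism must be below the population size")
        if self.max_selected is not None and self.max_selected < 1:
            raise ConfigError("max_selected must be >= 1")


def ga_select(X, y, config: GAConfig | None = None, seed: int = 0) -> SelectionResult:
    """Genetic-algorithm wavelength selection over binary masks."""
    cfg = config or GAConfig()
    Xm, yv, wl = _unpack(X, y)
    n = Xm.shape[1]
    if n == 1:
        return _finalize("ga", Xm, yv, [0], wl, [], seed, cfg.max_lv)
    rng = np.random.default_rng(seed)

    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                cache[key] = np.inf
            elif cfg.cv_folds == 0:
                rmsecv, lv = loo_rmsecv(Xm[:, idx], yv, cfg.max_lv)
                cache[key] = float(rmsecv[lv - 1])
            else:
                cache[key] = _subset_rmsecv(Xm, yv, idx, cfg.max_lv, cfg.cv_folds)
        return cache[key]

    def repair(mask):
        """Enforce non-emptiness and the optional cardinality cap."""
        if not mask.any():
            mask[rng.integers(n)] = True
        if cfg.max_selected is not None:
            on = np.flatnonzero(mask)
            if on.size > cfg.max_selected:
                drop = rng.choice(on, size=on.size - cfg.max_selected, replace=False)
                mask[drop] = False
        return mask

    pop = rng.random((cfg.population, n)) < cfg.init_prob
    pop = np.array([repair(row) for row in pop])
    scores = np.array([fitness(ind) for ind in pop])

    best_mask = pop[np.argmin(scores)].copy()
    best_score = float(scores.min())
    history = [best_score]

    for _ in range(cfg.generations):
        order = np.argsort(scores, kind="stable")
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population:
            picks = rng.integers(cfg.population, size=(2, cfg.tournament_size))
            pa = pop[picks[0][np.argmin(scores[picks[0]])]]
            pb = pop[picks[1][np.argmin(scores[picks[1]])]]
            if rng.random() < cfg.crossover_prob:  # uniform crossover
                take = rng.random(n) < 0.5
                child = np.where(take, pa, pb)
            else:
                child = pa.copy()
            flip = rng.random(n) < cfg.mutation_prob
            child = repair(child ^ flip)
            new_pop.append(child)
        pop = np.array(new_pop)
        scores = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score:
            best_score = float(scores[gen_best])
            best_mask = pop[gen_best].copy()
        history.append(best_score)

    return _finalize("ga", Xm, yv, np.flatnonzero(best_mask), wl, history, seed, cfg.max_lv)


# --------------------------------------------------------------------------
# competitive adaptive reweighted sampling
# --------------------------------------------------------------------------

def cars_edf(n_wavelengths: int, n_runs: int) -> np.ndarray:
    """The CARS exponentially decreasing retention fractions r_1..r_N.

    ``r_i = a * exp(-k * i)`` with a, k fixed by r_1 = 1 and r_N = 2/n.
    """
    if n_runs < 2:
        return np.ones(max(n_runs, 0))
    k = np.log(n_wavelengths / 2.0) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(
    X,
    y,
    n_runs: int = 100,
    max_lv: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    subset_fraction: float = 0.8,
) -> SelectionResult:
    """CARS wavelength selection (Monte Carlo runs 100, max LV 10, 10-fold CV)."""
    Xm, yv, wl = _unpack(X, y)
    m, n = Xm.shape
    if n < 3:
        raise SizeError("CARS needs at least 3 wavelengths")
    rng = np.random.default_rng(seed)
    ratios = cars_edf(n, n_runs)

    def coef_weights(rows, cols):
        Xs = Xm[np.ix_(rows, cols)]
        ys = yv[rows]
        Xc = Xs - Xs.mean(axis=0)
        yc = ys - ys.mean()
        comps = min(max_lv, Xs.shape[0] - 1, cols.size)
        from .pls import _nipals_path

        fit = _nipals_path(Xc, yc, comps)
        return np.abs(fit["b_path"][:, fit["n_components"] - 1])

    active = np.arange(n)
    history = []
    subsets = []
    n_sub = max(2, int(round(subset_fraction * m)))
    for i in range(n_runs):
        rows = rng.choice(m, size=n_sub, replace=False)
        w = coef_weights(rows, active)
        # enforced wavelength reduction by the EDF
        keep = max(2, int(round(ratios[i] * n)))
        if keep < active.size:
            order = np.argsort(-w, kind="stable")
            sel = np.sort(order[:keep])
            active, w = active[sel], w[sel]
        # adaptive reweighted sampling among survivors
        if w.sum() > 0 and active.size > 2:
            drawn = rng.choice(active.size, size=active.size, replace=True, p=w / w.sum())
            surv = np.unique(drawn)
            if surv.size >= 2:
                active = active[surv]
        subsets.append(active.copy())
        history.append(_subset_rmsecv(Xm, yv, active, max_lv, cv_folds))

    best_run = int(np.argmin(history))
    return _finalize("cars", Xm, yv, subsets[best_run], wl, history, seed, max_lv)


# --------------------------------------------------------------------------
# successive projections algorithm
# --------------------------------------------------------------------------

def _spa_chain(Xcal: np.ndarray, start: int, k_max: int) -> list:
    """Grow a chain of minimally collinear columns from ``start``.

    At each step every remaining column is projected orthogonally to the
    span of the chain; the column with the largest residual norm joins next
    (ties to the lowest index; exactly collinear columns are never added).
    """
    R = Xcal.copy()
    n = R.shape[1]
    chain = [start]
    v = R[:, start].copy()
    for _ in range(k_max - 1):
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        u = v / nv
        R = R - np.outer(u, u @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-10:
            break
        chain.append(nxt)
        v = R[:, nxt].copy()
    return chain


def spa_select(
    X,
    y,
    k_min: int = 5,
    k_max: int = 30,
    val_fraction: float = 0.3,
) -> SelectionResult:
    """SPA selection scored by MLR on an internal 70/30 Kennard-Stone split."""
    if k_min > k_max:
        raise ConfigError(f"k_min={k_min} > k_max={k_max}")
    Xm, yv, wl = _unpack(X, y)
    m, n = Xm.shape
    k_min = max(1, k_min)
    cal_idx = kennard_stone_indices(Xm, max(2, int(round((1 - val_fraction) * m))))
    val_idx = sorted(set(range(m)) - set(cal_idx))
    if not val_idx:
        raise SizeError("SPA internal split left no validation samples")
    Xcal, ycal = Xm[cal_idx], yv[cal_idx]
    Xval, yval = Xm[val_idx], yv[val_idx]
    k_cap = min(k_max, Xcal.shape[0] - 1, n)
    if k_cap > min(m - 1, n):
        raise ConfigError("k_max exceeds min(m-1, n)")

    def mlr_val_rmse(cols):
        A = np.column_stack([np.ones(len(cal_idx)), Xcal[:, cols]])
        coef, *_ = np.linalg.lstsq(A, ycal, rcond=None)
        pred = np.column_stack([np.ones(len(val_idx)), Xval[:, cols]]) @ coef
        return float(np.sqrt(np.mean((yval - pred) ** 2)))

    best = None
    history = []
    for start in range(n):
        chain = _spa_chain(Xcal, start, k_cap)
        for k in range(k_min, min(len(chain), k_cap) + 1):
            score = mlr_val_rmse(chain[:k])
            if best is None or score < best[0]:
                best = (score, list(chain[:k]))
        history.append(best[0] if best else np.inf)
    if best is None:
        raise SizeError("SPA found no chain of the requested length")
    max_lv = min(20, len(best[1]))
    return _finalize("spa", Xm, yv, best[1], wl, history, None, max_lv)


# --------------------------------------------------------------------------
# synergy-interval PLS
# --------------------------------------------------------------------------

def sipls_intervals(n: int, n_intervals: int) -> list:
    """Contiguous partition of n columns; the remainder goes to the leading
    intervals (387 columns over 20 intervals -> 7 of 20 then 13 of 19)."""
    if n_intervals > n:
        raise ConfigError(f"cannot split {n} columns into {n_intervals} intervals")
    base, rem = divmod(n, n_intervals)
    sizes = [base + 1] * rem + [base] * (n_intervals - rem)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_intervals)]


def sipls_select(
    X,
    y,
    n_intervals: int = 20,
    combo_sizes=(2, 3, 4),
    cv_folds: int = 5,
    max_lv: int = 20,
) -> SelectionResult:
    """Exhaustive synergy-interval search over all interval combinations."""
    Xm, yv, wl = _unpack(X, y)
    n = Xm.shape[1]
    intervals = sipls_intervals(n, n_intervals)
    combo_sizes = sorted(set(int(c) for c in combo_sizes))
    if any(c < 1 or c > n_intervals for c in combo_sizes):
        raise ConfigError("combination sizes must lie in [1, n_intervals]")

    best = None
    history = []
    for size in combo_sizes:
        for combo in itertools.combinations(range(n_intervals), size):
            idx = np.concatenate([intervals[i] for i in combo])
            score = _subset_rmsecv(Xm, yv, idx, max_lv, cv_folds)
            if best is None or score < best[0]:
                best = (score, idx, combo)
            history.append(best[0])
    result = _finalize("sipls", Xm, yv, best[1], wl, history, None, max_lv)
    return result
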