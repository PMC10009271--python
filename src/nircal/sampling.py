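"""Kennard-Stone calibration/prediction splitting.

The KS algorithm is a deterministic greedy max-min design: seed with the two
most distant samples (Euclidean distance between spectra), then repeatedly
add the sample whose minimum distance to the already-selected set is
largest.  The selected samples form the calibration set; the remainder is
the prediction (validation) set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SpectraSet
from .exceptions import SizeError

__all__ = ["SplitResult", "kennard_stone_split", "kennard_stone_indices"]


@dataclass(frozen=True)
class SplitResult:
    calibration_indices: tuple  # in pick order
    prediction_indices: tuple  # ascending
    fraction: float

    def to_dict(self) -> dict:
        return {
            "calibration": list(self.calibration_indices),
            "prediction": list(self.prediction_indices),
            "fraction": self.fraction,
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def kennard_stone_indices(X: np.ndarray, n_select: int) -> list:
    """Greedy max-min selection of ``n_select`` row indices of ``X``.

    Ties in the max-min distance are broken toward the lowest index, which
    makes the output fully deterministic.  Duplicate rows are legal: once
    all remaining min-distances are zero the lowest-index rows fill in.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 2 <= n_select <= m:
        raise SizeError(f"cannot select {n_select} of {m} samples")
    # seed pair: first argmax of the pairwise distance matrix in row-major
    # order == lowest (i, j) among ties
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    np.fill_diagonal(d2, np.inf)
    min_d2 = np.minimum(d2[:, i], d2[:, j])
    min_d2[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d2))  # first occurrence == lowest index
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[:, nxt])
        min_d2[nxt] = -np.inf
    return selected


def kennard_stone_split(s, fraction: float) -> SplitResult:
    """Split a :class:`SpectraSet` (or raw matrix) into calibration/prediction.

    The calibration size is the nearest integer to ``fraction * m`` (half
    rounds up), never below 2; an all-calibration split is rejected because
    it leaves nothing to validate on.
    """
    X = s.absorbance if isinstance(s, SpectraSet) else np.asarray(s, dtype=float)
    m = X.shape[0]
    if m < 3:
        raise SizeError("Kennard-Stone split needs at least 3 samples")
    if not 0.0 < fraction < 1.0:
        raise SizeError(f"fraction must be in (0, 1), got {fraction}")
    n_cal = max(2, _round_half_up(fraction * m))
    if n_cal >= m:
        raise SizeError(
            f"calibration size {n_cal} leaves an empty prediction set (m={m})"
        )
    cal = kennard_stone_indices(X, n_cal)
    pred = sorted(set(range(m)) - set(cal))
    return SplitResult(tuple(cal), tuple(pred), float(fraction))
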