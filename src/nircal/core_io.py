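"""Spectra and reference-value containers plus delimited-text I/O.

The canonical on-disk format is plain CSV:

* spectra: first column ``id``, remaining column headers are the numeric
  wavelength grid in nm, one sample per row, cells are absorbance;
* reference values: columns ``id``, ``lignin_mg_per_g`` and ``batch``.

Absorbance is the working domain throughout (log(1/R)); nothing in the
package converts raw reflectance counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError, GridError

__all__ = [
    "SpectraSet",
    "ReferenceSet",
    "load_dataset",
    "write_dataset",
    "trim_wavelengths",
    "average_replicates",
]


@dataclass(frozen=True)
class SpectraSet:
    """An m x n block of absorbance spectra on a common wavelength grid.

    Attributes
    ----------
    wavelengths : ndarray, shape (n,)
        Strictly increasing grid in nm.
    absorbance : ndarray, shape (m, n)
        Unitless absorbance, one sample per row.
    sample_ids : tuple of str
        Unique identifiers, one per row.
    batch_label : str
        Free-text batch tag (e.g. ``"A"``).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: tuple
    batch_label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.ndim == 1:
            ab = ab[None, :]
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if wl.ndim != 1 or wl.size < 2:
            raise GridError("wavelength grid must be 1-D with at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise GridError("wavelength grid must be strictly increasing")
        if ab.shape[0] < 1:
            raise DataError("at least one sample row required")
        if ab.shape[1] != wl.size:
            raise DataError(
                f"absorbance has {ab.shape[1]} columns but grid has {wl.size} points"
            )
        if len(self.sample_ids) != ab.shape[0]:
            raise DataError("sample_ids length does not match number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise DataError("spectra contain NaN or infinite entries")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def take(self, row_indices) -> "SpectraSet":
        """Return a new set restricted to the given sample rows (order kept)."""
        idx = np.asarray(row_indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            batch_label=self.batch_label,
        )

    def with_absorbance(self, new_absorbance: np.ndarray) -> "SpectraSet":
        return replace(self, absorbance=np.asarray(new_absorbance, dtype=float))


@dataclass(frozen=True)
class ReferenceSet:
    """Per-sample lignin content in mg per g dry flesh, aligned by id."""

    values: np.ndarray
    sample_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if v.ndim != 1:
            raise DataError("reference values must be a vector")
        if len(self.sample_ids) != v.size:
            raise DataError("sample_ids length does not match number of values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if not np.all(np.isfinite(v)):
            raise DataError("reference values contain NaN or infinite entries")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def take(self, row_indices) -> "ReferenceSet":
        idx = np.asarray(row_indices, dtype=int)
        return ReferenceSet(
            values=self.values[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )


def load_dataset(spectra_path, reference_path) -> tuple:
    """Read a spectra CSV and a reference CSV and return an id-aligned pair.

    Sample order follows the spectra file; the reference table is re-ordered
    to match.  Raises :class:`AlignmentError` if the id sets differ.
    """
    spectra_path = Path(spectra_path)
    reference_path = Path(reference_path)
    sdf = pd.read_csv(spectra_path, float_precision="round_trip")
    if sdf.columns[0] != "id":
        raise DataError(f"{spectra_path}: first column must be 'id'")
    try:
        wavelengths = np.array([float(c) for c in sdf.columns[1:]])
    except ValueError as exc:
        raise GridError(f"{spectra_path}: non-numeric wavelength header") from exc
    ids = [str(s) for s in sdf["id"].tolist()]
    absorbance = sdf.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(absorbance).any():
        raise DataError(f"{spectra_path}: NaN cells present")

    rdf = pd.read_csv(reference_path, float_precision="round_trip")
    for col in ("id", "lignin_mg_per_g"):
        if col not in rdf.columns:
            raise DataError(f"{reference_path}: missing column '{col}'")
    rdf = rdf.assign(id=rdf["id"].astype(str)).set_index("id")
    missing = [i for i in ids if i not in rdf.index]
    extra = [i for i in rdf.index if i not in set(ids)]
    if missing or extra:
        raise AlignmentError(
            f"id mismatch between spectra and reference files "
            f"(missing={missing[:5]}, extra={extra[:5]})"
        )
    values = rdf.loc[ids, "lignin_mg_per_g"].to_numpy(dtype=float)
    batch = ""
    if "batch" in rdf.columns:
        batches = set(rdf["batch"].astype(str))
        batch = batches.pop() if len(batches) == 1 else ""
    spectra = SpectraSet(wavelengths, absorbance, tuple(ids), batch_label=batch)
    reference = ReferenceSet(values, tuple(ids))
    return spectra, reference


def write_dataset(spectra: SpectraSet, reference: ReferenceSet, spectra_path, reference_path):
    """Write the pair back in the canonical CSV layout (mirrors the reader)."""
    if spectra.sample_ids != reference.sample_ids:
        raise AlignmentError("spectra and reference ids differ")
    sdf = pd.DataFrame(spectra.absorbance, columns=[repr(float(w)) for w in spectra.wavelengths])
    sdf.insert(0, "id", list(spectra.sample_ids))
    sdf.to_csv(spectra_path, index=False, float_format="%.17g")
    rdf = pd.DataFrame(
        {
            "id": list(reference.sample_ids),
            "lignin_mg_per_g": reference.values,
            "batch": spectra.batch_label,
        }
    )
    rdf.to_csv(reference_path, index=False, float_format="%.17g")


def trim_wavelengths(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep exactly the columns with lo <= wavelength <= hi (both ends inclusive)."""
    if not lo < hi:
        raise GridError(f"invalid trim range [{lo}, {hi}]")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise GridError(f"no wavelengths survive trimming to [{lo}, {hi}]")
    return SpectraSet(
        wavelengths=s.wavelengths[mask],
        absorbance=s.absorbance[:, mask],
        sample_ids=s.sample_ids,
        batch_label=s.batch_label,
    )


def average_replicates(replicates: Sequence[SpectraSet]) -> SpectraSet:
    """Element-wise mean over replicate acquisitions of the same samples.

    All replicates must share the wavelength grid and the sample ids in the
    same order (e.g. the 9 positions x 3 scans of one measurement session).
    """
    if len(replicates) == 0:
        raise DataError("need at least one replicate")
    first = replicates[0]
    for r in replicates[1:]:
        if r.wavelengths.shape != first.wavelengths.shape or not np.array_equal(
            r.wavelengths, first.wavelengths
        ):
            raise GridError("replicate wavelength grids differ")
        if r.sample_ids != first.sample_ids:
            raise AlignmentError("replicate sample ids differ")
    stacked = np.stack([r.absorbance for r in replicates], axis=0)
    return SpectraSet(
        wavelengths=first.wavelengths,
        absorbance=stacked.mean(axis=0),
        sample_ids=first.sample_ids,
        batch_label=first.batch_label,
    )
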