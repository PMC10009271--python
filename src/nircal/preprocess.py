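"""Spectral pretreatments: SNV, MSC and Savitzky-Golay derivatives.

All three operate row-wise on a :class:`~nircal.core_io.SpectraSet` and
return a new set on the same grid.  SNV and the derivatives are
parameter-free per spectrum; MSC fits a per-spectrum gain/offset against a
reference spectrum, and that reference (the calibration-set mean) must be
stored and reused when correcting prediction-set spectra so that no
information flows from test to train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core_io import SpectraSet
from .exceptions import ConfigError, DegenerateDataError, GridError

__all__ = ["PreprocessSpec", "snv", "msc", "msc_reference", "sg_derivative", "apply_preprocess"]

_METHODS = ("none", "snv", "msc", "sg_derivative")


@dataclass(frozen=True)
class PreprocessSpec:
    """Serializable description of one pretreatment.

    ``sg_derivative`` follows the common chemometric parameterisation:
    ``derivative_order`` 1 or 2, fitted polynomial of ``poly_order`` over a
    moving window of ``window_points`` (odd) grid points.
    """

    method: str = "none"
    derivative_order: int = 1
    poly_order: int = 1
    window_points: int = 11

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigError(f"unknown preprocessing method {self.method!r}")
        if self.method == "sg_derivative":
            if self.window_points % 2 == 0 or self.window_points < self.poly_order + 1:
                raise ConfigError("window_points must be odd and >= poly_order + 1")
            if self.derivative_order not in (1, 2):
                raise ConfigError("derivative_order must be 1 or 2")
            if self.derivative_order > self.poly_order:
                raise ConfigError("derivative_order cannot exceed poly_order")

    @property
    def label(self) -> str:
        if self.method == "sg_derivative":
            return f"{self.derivative_order}-der({self.window_points})"
        return self.method

    def to_dict(self) -> dict:
        d = {"method": self.method}
        if self.method == "sg_derivative":
            d.update(
                derivative_order=self.derivative_order,
                poly_order=self.poly_order,
                window_points=self.window_points,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**d)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and scale each spectrum to unit spread.

    Uses the sample standard deviation (divisor m-1).  A spectrum with no
    spread cannot be scaled and raises :class:`DegenerateDataError` naming
    the offending sample.
    """
    x = s.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] < 1e-12)
    if bad.size:
        raise DegenerateDataError(
            f"constant spectrum, SNV undefined for sample id {s.sample_ids[bad[0]]!r}"
        )
    return s.with_absorbance((x - mean) / sd)


def msc_reference(s: SpectraSet) -> np.ndarray:
    """The default MSC reference: the column-wise mean spectrum of the set."""
    return s.absorbance.mean(axis=0)


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x_i`` is regressed ``x_i = a_i + b_i * ref`` by ordinary
    least squares and corrected to ``(x_i - a_i) / b_i``.  ``reference``
    defaults to the mean spectrum of ``s``; pass the calibration-set
    reference when correcting new data.
    """
    x = s.absorbance
    ref = msc_reference(s) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (x.shape[1],):
        raise DegenerateDataError("MSC reference length does not match the grid")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom < 1e-12:
        raise DegenerateDataError("constant MSC reference spectrum")
    slopes = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(slopes) < 1e-12)
    if bad.size:
        raise DegenerateDataError(
            f"MSC slope ~0 for sample id {s.sample_ids[bad[0]]!r}"
        )
    intercepts = x.mean(axis=1) - slopes * ref.mean()
    corrected = (x - intercepts[:, None]) / slopes[:, None]
    return s.with_absorbance(corrected)


def sg_derivative(
    s: SpectraSet,
    derivative_order: int = 1,
    poly_order: int = 1,
    window_points: int = 11,
) -> SpectraSet:
    """Savitzky-Golay derivative in absorbance per nm (per nm^2 for order 2).

    Requires an evenly spaced grid; the output keeps all n points, with the
    edge values taken from the polynomial fitted to the first/last window.
    """
    spec = PreprocessSpec(
        method="sg_derivative",
        derivative_order=derivative_order,
        poly_order=poly_order,
        window_points=window_points,
    )
    n = s.n_wavelengths
    if spec.window_points > n:
        raise GridError(f"window of {spec.window_points} points exceeds grid size {n}")
    steps = np.diff(s.wavelengths)
    delta = steps.mean()
    if np.max(np.abs(steps - delta)) > 1e-9 * max(abs(delta), 1.0):
        raise GridError("Savitzky-Golay derivative requires an evenly spaced grid")
    out = savgol_filter(
        s.absorbance,
        window_length=spec.window_points,
        polyorder=spec.poly_order,
        deriv=spec.derivative_order,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return s.with_absorbance(out)


def apply_preprocess(
    spec: PreprocessSpec, s: SpectraSet, fitted_reference: np.ndarray | None = None
):
    """Apply ``spec`` to ``s``; returns ``(corrected, fitted_reference)``.

    The second element is only meaningful for MSC: when ``fitted_reference``
    is None the reference is fitted on ``s`` (calibration mode) and returned
    for later reuse on prediction data.
    """
    if spec.method == "none":
        return s, None
    if spec.method == "snv":
        return snv(s), None
    if spec.method == "msc":
        ref = msc_reference(s) if fitted_reference is None else fitted_reference
        return msc(s, reference=ref), ref
    return (
        sg_derivative(s, spec.derivative_order, spec.poly_order, spec.window_points),
        None,
    )
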