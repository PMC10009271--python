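"""Seeded generator of multi-batch NIR spectra with ground truth.

The generator emulates the structure of a multi-batch fruit-lignin NIR
study: four batches of 160/120/104/128 pear samples, absorbance spectra on
387 evenly spaced points over 1033-2300 nm, nine measurement positions x
three scans averaged per sample, per-sample multiplicative/additive scatter,
and batch-level drift (wavelength shift, global gain, baseline offset, a new
interferent band, measurement noise).

The optical model is linear (Beer-Lambert-like) in absorbance:

    a(lambda) = lc * s_lignin(lambda) + sum_k c_k * s_k(lambda)
                + baseline(lambda) [+ interferent]

where every pure-component spectrum ``s`` is a sum of Gaussian bands.  The
lignin bands sit near 1160, 1198, 1420, 1680 and 2270 nm - overtone and
combination bands of the C-H / O-H / C=O groups that carry lignin
information in real NIR spectra.  Scatter enters multiplicatively and
additively, so SNV and MSC are the appropriate corrections, mirroring why
those pretreatments win on real fruit spectra.

Each batch records its ground truth (informative wavelength columns,
per-sample scatter parameters, drift parameters) so selection and transfer
algorithms can be validated against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import ReferenceSet, SpectraSet, average_replicates
from .exceptions import ConfigError

__all__ = [
    "GridSpec",
    "Band",
    "ComponentSpec",
    "DriftSpec",
    "ScatterSpec",
    "BatchSpec",
    "GeneratorConfig",
    "SyntheticBatch",
    "default_study_config",
    "single_band_config",
    "generate_batch",
    "generate_study",
    "batch_seeds",
]


@dataclass(frozen=True)
class GridSpec:
    lo: float = 1033.0
    hi: float = 2300.0
    n_points: int = 387

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)


@dataclass(frozen=True)
class Band:
    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float

    def profile(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.width_nm) ** 2)


@dataclass(frozen=True)
class ComponentSpec:
    """A non-analyte constituent (water, sugars) with random concentration."""

    name: str
    bands: tuple
    conc_mean: float = 1.0
    conc_sd: float = 0.1


@dataclass(frozen=True)
class DriftSpec:
    """Batch-level measurement drift applied to every sample of a batch."""

    shift_nm: float = 0.0
    gain: float = 1.0
    baseline_offset: float = 0.0
    interferent_amplitude: float = 0.0
    noise_sd: float = 0.0015  # per-scan absorbance noise

    def to_dict(self) -> dict:
        return {
            "shift_nm": self.shift_nm,
            "gain": self.gain,
            "baseline_offset": self.baseline_offset,
            "interferent_amplitude": self.interferent_amplitude,
            "noise_sd": self.noise_sd,
        }


@dataclass(frozen=True)
class ScatterSpec:
    """Sample-wise and replicate-wise scatter.

    ``gain_sd``/``offset_sd`` are per-sample multiplicative/additive scatter
    (particle size, surface geometry); the replicate-level terms vary across
    the position/scan acquisitions of one sample; ``sample_shift_sd`` is a
    per-sample wavelength registration jitter in nm (probe repositioning),
    an irreducible error source that no row-wise pretreatment removes."""

    gain_sd: float = 0.15
    offset_sd: float = 0.03
    replicate_gain_sd: float = 0.02
    replicate_offset_sd: float = 0.005
    sample_shift_sd: float = 0.30


@dataclass(frozen=True)
class BatchSpec:
    name: str
    n_samples: int
    lc_mean: float  # mg/g
    lc_sd: float  # mg/g
    lc_range: tuple  # (lo, hi) mg/g
    drift: DriftSpec = field(default_factory=DriftSpec)

    def __post_init__(self):
        lo, hi = self.lc_range
        if not lo < self.lc_mean < hi:
            raise ConfigError(f"batch {self.name}: lc_range must bracket lc_mean")
        if hi - lo <= 0:
            raise ConfigError(f"batch {self.name}: zero-width lc_range")
        if self.n_samples < 3:
            raise ConfigError(f"batch {self.name}: need at least 3 samples")
        if self.lc_sd < 0 or self.drift.noise_sd < 0:
            raise ConfigError(f"batch {self.name}: SDs must be >= 0")


# lignin overtone/combination band priors (nm): third overtone C-H near
# 1160/1198, O-H/C-H combination near 1420, first overtone C-H near 1680,
# C-H+C-H combination near 2270
_DEFAULT_LIGNIN_BANDS = (
    Band(1160.0, 18.0, 1.00),
    Band(1198.0, 15.0, 0.70),
    Band(1420.0, 25.0, 0.90),
    Band(1680.0, 22.0, 0.80),
    Band(2270.0, 20.0, 0.60),
)

_DEFAULT_COMPONENTS = (
    ComponentSpec(
        "water",
        bands=(Band(1450.0, 35.0, 0.25), Band(1940.0, 45.0, 0.33)),
        conc_mean=1.0,
        conc_sd=0.08,
    ),
    ComponentSpec(
        "sugars",
        bands=(Band(1580.0, 30.0, 0.08), Band(1730.0, 25.0, 0.10), Band(2100.0, 35.0, 0.14)),
        conc_mean=1.0,
        conc_sd=0.12,
    ),
    # a cell-wall-like constituent whose bands overlap the lignin bands:
    # the collinear interference that keeps the calibration realistic
    ComponentSpec(
        "cellwall",
        bands=(
            Band(1180.0, 22.0, 0.30),
            Band(1440.0, 28.0, 0.28),
            Band(1700.0, 25.0, 0.24),
            Band(2280.0, 22.0, 0.18),
        ),
        conc_mean=1.0,
        conc_sd=0.20,
    ),
)


@dataclass(frozen=True)
class GeneratorConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    batch_specs: tuple = ()
    lignin_bands: tuple = _DEFAULT_LIGNIN_BANDS
    lignin_amp_per_mg: float = 0.0015  # AU per (mg/g) at band amplitude 1
    components: tuple = _DEFAULT_COMPONENTS
    baseline_coeffs: tuple = (0.35, 1.5e-4, -4.0e-8)  # a + b*(wl-lo) + c*(wl-lo)^2
    # batch-drift interferent sits on top of the 1680 nm lignin band, so its
    # growth forces a genuine coefficient adjustment, not just a bias shift
    interferent_band: Band = Band(1690.0, 25.0, 1.0)
    scatter: ScatterSpec = field(default_factory=ScatterSpec)
    n_positions: int = 9
    n_scans: int = 3
    reference_noise_sd: float = 0.1  # mg/g, magnitude of wet-chemistry error
    seed: int = 0

    def batch(self, name: str) -> BatchSpec:
        for b in self.batch_specs:
            if b.name == name:
                return b
        raise ConfigError(f"no batch named {name!r} in config")

    def lignin_profile(self, wl: np.ndarray) -> np.ndarray:
        """Pure-component lignin response in AU per (mg/g)."""
        prof = np.zeros_like(wl)
        for band in self.lignin_bands:
            prof += band.profile(wl)
        return self.lignin_amp_per_mg * prof

    def informative_indices(self) -> np.ndarray:
        """Columns where the lignin response exceeds 10% of its maximum."""
        prof = self.lignin_profile(self.grid.wavelengths())
        return np.flatnonzero(prof > 0.10 * prof.max())


@dataclass(frozen=True)
class SyntheticBatch:
    spectra: SpectraSet
    references: ReferenceSet
    truth: dict


def default_study_config(seed: int = 0) -> GeneratorConfig:
    """The four-batch study layout: batch A drift-free (the master batch),
    batches B-D with progressively stronger drift in a consistent direction,
    and batch D with a compressed lignin spread."""
    batches = (
        BatchSpec("A", 160, 77.87, 1.22, (75.05, 81.04), DriftSpec()),
        BatchSpec(
            "B", 120, 77.75, 1.18, (74.78, 80.80),
            DriftSpec(shift_nm=0.5, gain=1.010, baseline_offset=0.005,
                      interferent_amplitude=0.004),
        ),
        BatchSpec(
            "C", 104, 78.03, 1.19, (75.48, 81.42),
            DriftSpec(shift_nm=2.5, gain=1.025, baseline_offset=0.012,
                      interferent_amplitude=0.020),
        ),
        BatchSpec(
            "D", 128, 77.93, 0.55, (76.43, 79.38),
            DriftSpec(shift_nm=4.5, gain=1.045, baseline_offset=0.020,
                      interferent_amplitude=0.040),
        ),
    )
    return GeneratorConfig(batch_specs=batches, seed=seed)


def single_band_config(
    n_samples: int = 120,
    n_points: int = 120,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> GeneratorConfig:
    """A small one-batch layout with a single narrow lignin band.

    Used to validate wavelength-selection methods against a known
    informative region: only a handful of contiguous columns carry the
    analyte signal; the rest carries baseline, noise and two nuisance
    constituents whose variance is unrelated to the analyte — so discarding
    the uninformative columns genuinely improves cross-validation.
    """
    grid = GridSpec(1100.0, 1500.0, n_points)
    spacing = (grid.hi - grid.lo) / (n_points - 1)
    band = Band(1300.0, 2.8 * spacing, 1.0)
    nuisance = (
        ComponentSpec(
            "nuisance_low",
            bands=(Band(1160.0, 6.0 * spacing, 0.15), Band(1205.0, 4.0 * spacing, 0.10)),
            conc_mean=1.0,
            conc_sd=0.30,
        ),
        ComponentSpec(
            "nuisance_high",
            bands=(Band(1400.0, 5.0 * spacing, 0.12), Band(1455.0, 4.0 * spacing, 0.10)),
            conc_mean=1.0,
            conc_sd=0.30,
        ),
    )
    batch = BatchSpec(
        "band", n_samples, 77.9, 1.2, (74.0, 82.0), DriftSpec(noise_sd=noise_sd)
    )
    return GeneratorConfig(
        grid=grid,
        batch_specs=(batch,),
        lignin_bands=(band,),
        lignin_amp_per_mg=0.03,
        components=nuisance,
        baseline_coeffs=(0.30, 5.0e-5, 0.0),
        scatter=ScatterSpec(0.0, 0.0, 0.0, 0.0, 0.0),
        n_positions=1,
        n_scans=1,
        reference_noise_sd=0.05,
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if not lo < hi:
        raise ConfigError("truncation interval has zero width")
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_batch(config: GeneratorConfig, batch_name: str, seed: int | None = None) -> SyntheticBatch:
    """Generate one batch: draw concentrations, mix pure spectra, apply batch
    drift, then simulate and average the position/scan replicates."""
    spec = config.batch(batch_name)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wl = config.grid.wavelengths()
    m, n = spec.n_samples, wl.size

    lc = _truncated_normal(rng, spec.lc_mean, spec.lc_sd, *spec.lc_range, size=m)
    lignin_profile = config.lignin_profile(wl)
    clean = lc[:, None] * lignin_profile[None, :]

    concentrations = {"lignin": lc}
    for comp in config.components:
        conc = rng.normal(comp.conc_mean, comp.conc_sd, m).clip(min=0.0)
        concentrations[comp.name] = conc
        prof = np.zeros(n)
        for band in comp.bands:
            prof += band.profile(wl)
        clean += conc[:, None] * prof[None, :]

    a0, a1, a2 = config.baseline_coeffs
    rel = wl - config.grid.lo
    clean += a0 + a1 * rel + a2 * rel**2

    drift = spec.drift
    if drift.interferent_amplitude != 0.0:
        interf_conc = drift.interferent_amplitude * rng.normal(1.0, 0.1, m).clip(min=0.0)
        concentrations["interferent"] = interf_conc
        clean += interf_conc[:, None] * config.interferent_band.profile(wl)[None, :]
    sc = config.scatter
    sample_shift = (
        rng.normal(0.0, sc.sample_shift_sd, m) if sc.sample_shift_sd > 0 else np.zeros(m)
    )
    total_shift = drift.shift_nm + sample_shift
    if np.any(total_shift != 0.0):
        # the instrument reports the value at lambda + shift under label lambda
        shifted = np.empty_like(clean)
        for i in range(m):
            shifted[i] = np.interp(wl + total_shift[i], wl, clean[i])
        clean = shifted
    clean = drift.gain * clean + drift.baseline_offset

    sample_gain = rng.normal(1.0, sc.gain_sd, m) if sc.gain_sd > 0 else np.ones(m)
    sample_offset = rng.normal(0.0, sc.offset_sd, m) if sc.offset_sd > 0 else np.zeros(m)
    base = sample_gain[:, None] * clean + sample_offset[:, None]

    ids = tuple(f"{spec.name}{i + 1:03d}" for i in range(m))
    replicates = []
    n_rep = config.n_positions * config.n_scans
    for _ in range(n_rep):
        g = rng.normal(1.0, sc.replicate_gain_sd, m)[:, None] if sc.replicate_gain_sd > 0 else 1.0
        o = rng.normal(0.0, sc.replicate_offset_sd, m)[:, None] if sc.replicate_offset_sd > 0 else 0.0
        noise = rng.normal(0.0, drift.noise_sd, (m, n)) if drift.noise_sd > 0 else 0.0
        replicates.append(
            SpectraSet(wl, g * base + o + noise, ids, batch_label=spec.name)
        )
    spectra = average_replicates(replicates)

    if config.reference_noise_sd > 0:
        y = lc + rng.normal(0.0, config.reference_noise_sd, m)
        y = np.clip(y, *spec.lc_range)
    else:
        y = lc.copy()
    references = ReferenceSet(y, ids)

    truth = {
        "informative_indices": config.informative_indices(),
        "lc_true": lc,
        "concentrations": concentrations,
        "sample_gain": sample_gain,
        "sample_offset": sample_offset,
        "sample_shift_nm": sample_shift,
        "drift": drift.to_dict(),
    }
    return SyntheticBatch(spectra=spectra, references=references, truth=truth)


def batch_seeds(master_seed: int, n_batches: int) -> list:
    """Independent per-batch seeds derived from one master seed.

    Splitting rule: ``numpy.random.SeedSequence(master_seed)`` expanded to
    ``n_batches`` 31-bit integers, taken in batch order.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n_batches)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_study(config: GeneratorConfig, seed: int | None = None) -> list:
    """Generate every batch in the config with independent derived seeds."""
    if len(config.batch_specs) < 2:
        raise ConfigError("a study needs at least 2 batches")
    master_seed = config.seed if seed is None else seed
    seeds = batch_seeds(master_seed, len(config.batch_specs))
    return [
        generate_batch(config, b.name, seed=s)
        for b, s in zip(config.batch_specs, seeds)
    ]
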