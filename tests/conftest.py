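import numpy as np
import pytest

from nircal.core_io import ReferenceSet, SpectraSet
from nircal.synthdata import (
    BatchSpec,
    ComponentSpec,
    Band,
    DriftSpec,
    GeneratorConfig,
    GridSpec,
    ScatterSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra():
    """A tiny well-formed SpectraSet for structural tests."""
    wl = np.array([1100.0, 1200.0, 1300.0, 1400.0])
    ab = np.array(
        [
            [0.10, 0.20, 0.30, 0.40],
            [0.15, 0.25, 0.35, 0.45],
            [0.40, 0.30, 0.20, 0.10],
        ]
    )
    return SpectraSet(wl, ab, ("s1", "s2", "s3"), batch_label="t")


def tiny_study_config(seed: int = 0, **drift_overrides) -> GeneratorConfig:
    """A scaled-down two-to-four-batch study for structural pipeline tests.

    Same physics as the default study but fewer samples, fewer replicates
    and a coarser grid, so a full pipeline run takes well under a second.
    """
    drifts = {
        "B": DriftSpec(shift_nm=0.5, gain=1.01, baseline_offset=0.005,
                       interferent_amplitude=0.004),
        "C": DriftSpec(shift_nm=2.5, gain=1.025, baseline_offset=0.012,
                       interferent_amplitude=0.020),
        "D": DriftSpec(shift_nm=4.5, gain=1.045, baseline_offset=0.020,
                       interferent_amplitude=0.040),
    }
    drifts.update(drift_overrides)
    batches = (
        BatchSpec("A", 40, 77.87, 1.22, (75.05, 81.04), DriftSpec()),
        BatchSpec("B", 30, 77.75, 1.18, (74.78, 80.80), drifts["B"]),
        BatchSpec("C", 26, 78.03, 1.19, (75.48, 81.42), drifts["C"]),
        BatchSpec("D", 32, 77.93, 0.55, (76.43, 79.38), drifts["D"]),
    )
    return GeneratorConfig(
        grid=GridSpec(1033.0, 2300.0, 130),
        batch_specs=batches,
        n_positions=3,
        n_scans=1,
        seed=seed,
    )


def noiseless_lignin_only_config(n_samples: int = 60, n_points: int = 50) -> GeneratorConfig:
    """Zero noise, zero scatter, zero drift, lignin as the only constituent:
    the spectra are exactly affine in the lignin content."""
    return GeneratorConfig(
        grid=GridSpec(1100.0, 1500.0, n_points),
        batch_specs=(
            BatchSpec("A", n_samples, 77.9, 1.2, (74.0, 82.0),
                      DriftSpec(noise_sd=0.0)),
        ),
        lignin_bands=(Band(1300.0, 40.0, 1.0),),
        components=(),
        scatter=ScatterSpec(0.0, 0.0, 0.0, 0.0, 0.0),
        n_positions=1,
        n_scans=1,
        reference_noise_sd=0.0,
    )


def as_xy(batch):
    """Convenience: (X, y) arrays of a SyntheticBatch."""
    return batch.spectra.absorbance, batch.references.values


@pytest.fixture
def reference_for(small_spectra):
    return ReferenceSet(np.array([77.0, 78.0, 79.0]), small_spectra.sample_ids)
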