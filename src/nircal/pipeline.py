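"""Experiment orchestration: master-model building and multi-batch transfer.

Two experiments mirror the study design:

* :func:`run_master_experiment` — on the master batch, compare spectral
  pretreatments on the full spectrum, then compare wavelength-selection
  methods on the winning pretreatment, and persist the winning PLSR model.
* :func:`run_transfer_experiment` — apply the master model to each later
  batch directly, then update it with independent and sequential SS-FPME
  and tabulate Rp / RMSEP for all three routes per batch.

Every row of a report is recomputable from the persisted model and the
(seeded) data; reports carry the config hash and seed as provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthdata
from .core_io import SpectraSet
from .exceptions import AlignmentError, ConfigError, NircalError
from .pls import PLSModel, fit_pls, loo_rmsecv, predict, regression_metrics
from .preprocess import PreprocessSpec, apply_preprocess
from .sampling import SplitResult, kennard_stone_split
from .ssfpme import run_update_scheme
from .varsel import GAConfig, cars_select, ga_select, sipls_select, spa_select

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "MasterRecord",
    "run_master_experiment",
    "run_transfer_experiment",
    "run_study",
]

logger = logging.getLogger(__name__)

DEFAULT_PREPROCESS_CANDIDATES = (
    PreprocessSpec("none"),
    PreprocessSpec("sg_derivative", derivative_order=1, poly_order=1, window_points=11),
    PreprocessSpec("sg_derivative", derivative_order=2, poly_order=2, window_points=11),
    PreprocessSpec("snv"),
    PreprocessSpec("msc"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the two experiments; YAML-serializable."""

    generator: synthdata.GeneratorConfig = field(
        default_factory=synthdata.default_study_config
    )
    preprocess_candidates: tuple = DEFAULT_PREPROCESS_CANDIDATES
    varsel_methods: tuple = ({"method": "spa"},)  # e.g. ({"method": "ga", ...}, ...)
    master_fraction: float = 0.60
    update_fraction: float = 0.40
    rth: float = 0.95
    max_lv: int = 20
    seed: int = 0
    split_on: str = "preprocessed"  # or "raw"
    output_dir: str | None = None

    def __post_init__(self):
        for f in (self.master_fraction, self.update_fraction):
            if not 0.0 < f < 1.0:
                raise ConfigError("split fractions must lie in (0, 1)")
        if not self.preprocess_candidates:
            raise ConfigError("need at least one preprocessing candidate")
        if self.split_on not in ("preprocessed", "raw"):
            raise ConfigError("split_on must be 'preprocessed' or 'raw'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess_candidates"] = [p.to_dict() for p in self.preprocess_candidates]
        d["varsel_methods"] = [dict(v) for v in self.varsel_methods]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        if "generator" in d:
            kwargs["generator"] = _generator_from_dict(d["generator"])
        if "preprocess_candidates" in d:
            kwargs["preprocess_candidates"] = tuple(
                PreprocessSpec.from_dict(p) for p in d["preprocess_candidates"]
            )
        if "varsel_methods" in d:
            kwargs["varsel_methods"] = tuple(d["varsel_methods"])
        for key in ("master_fraction", "update_fraction", "rth", "max_lv", "seed",
                    "split_on", "output_dir"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def _generator_from_dict(d) -> synthdata.GeneratorConfig:
    if d in (None, "default_study"):
        return synthdata.default_study_config()
    grid = synthdata.GridSpec(**d.get("grid", {}))
    batches = []
    for b in d.get("batch_specs", []):
        drift = synthdata.DriftSpec(**b.pop("drift", {}))
        b["lc_range"] = tuple(b["lc_range"])
        batches.append(synthdata.BatchSpec(drift=drift, **b))
    kwargs = {k: v for k, v in d.items() if k in (
        "lignin_amp_per_mg", "n_positions", "n_scans", "reference_noise_sd", "seed")}
    if "scatter" in d:
        kwargs["scatter"] = synthdata.ScatterSpec(**d["scatter"])
    return synthdata.GeneratorConfig(grid=grid, batch_specs=tuple(batches), **kwargs)


@dataclass(frozen=True)
class MasterRecord:
    """Everything needed to re-apply the master model to a new batch."""

    model: PLSModel
    preprocess_spec: PreprocessSpec
    msc_reference: np.ndarray | None
    wavelengths: np.ndarray  # the full trimmed grid the model expects
    batch_label: str
    split: SplitResult
    metrics: dict

    def to_dict(self) -> dict:
        d = self.model.to_dict()
        d["wavelength_nm"] = self.wavelengths[self.model.wavelength_indices].tolist()
        d["preprocessing_spec"] = self.preprocess_spec.to_dict()
        d["msc_reference"] = (
            None if self.msc_reference is None else self.msc_reference.tolist()
        )
        d["grid_nm"] = self.wavelengths.tolist()
        d["batch_label"] = self.batch_label
        d["split"] = self.split.to_dict()
        d["metrics"] = self.metrics
        return d

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "MasterRecord":
        d = json.loads(Path(path).read_text())
        split = d["split"]
        return cls(
            model=PLSModel.from_dict(d),
            preprocess_spec=PreprocessSpec.from_dict(d["preprocessing_spec"]),
            msc_reference=(
                None if d["msc_reference"] is None else np.asarray(d["msc_reference"])
            ),
            wavelengths=np.asarray(d["grid_nm"], dtype=float),
            batch_label=d["batch_label"],
            split=SplitResult(
                tuple(split["calibration"]), tuple(split["prediction"]), split["fraction"]
            ),
            metrics=d["metrics"],
        )


@dataclass
class ExperimentReport:
    rows: list
    provenance: dict
    master: MasterRecord | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save(self, csv_path=None, json_path=None):
        if csv_path:
            self.to_dataframe().to_csv(csv_path, index=False)
        if json_path:
            Path(json_path).write_text(
                json.dumps({"provenance": self.provenance, "rows": self.rows}, default=str)
            )


def _split_and_preprocess(spectra, references, spec: PreprocessSpec, fraction, split_on):
    """KS-split a batch and apply a pretreatment without test-to-train leaks.

    The KS distances are computed on the (whole-batch) preprocessed spectra
    by default; the MSC reference is then refitted on the calibration rows
    only and reused for the prediction rows.
    """
    if split_on == "preprocessed":
        whole, _ = apply_preprocess(spec, spectra)
        split = kennard_stone_split(whole, fraction)
    else:
        split = kennard_stone_split(spectra, fraction)
    cal_s = spectra.take(split.calibration_indices)
    pred_s = spectra.take(split.prediction_indices)
    cal_p, fitted_ref = apply_preprocess(spec, cal_s)
    pred_p, _ = apply_preprocess(spec, pred_s, fitted_reference=fitted_ref)
    y_cal = references.take(split.calibration_indices)
    y_pred = references.take(split.prediction_indices)
    return split, cal_p, y_cal, pred_p, y_pred, fitted_ref


def _evaluate_subset(cal_X, y_cal, pred_X, y_pred, indices, max_lv):
    """Fit PLS on a wavelength subset (LV by LOO RMSECV) and score both sets."""
    idx = np.asarray(indices, dtype=int)
    rmsecv, lv = loo_rmsecv(cal_X[:, idx], y_cal, max_lv)
    model = fit_pls(cal_X[:, idx], y_cal, lv, wavelength_indices=idx,
                    keep_decomposition=False)
    cal_metrics = regression_metrics(
        y_cal, predict(model, cal_X[:, idx]).y_hat, mode="calibration"
    )
    pred_metrics = regression_metrics(
        y_pred, predict(model, pred_X[:, idx]).y_hat, mode="prediction"
    )
    return model, {
        "n_wavelengths": int(idx.size),
        "n_lv": int(lv),
        "rc": cal_metrics.r_as_printed,
        "rc_pearson": cal_metrics.pearson_r,
        "rmsecv": float(rmsecv[lv - 1]),
        "rp": pred_metrics.r_as_printed,
        "rp_pearson": pred_metrics.pearson_r,
        "rmsep": pred_metrics.rmse,
    }


_SELECTORS = {"ga", "cars", "spa", "sipls"}


def _run_selector(method_cfg: dict, X, y, seed: int):
    cfg = dict(method_cfg)
    method = cfg.pop("method")
    if method not in _SELECTORS:
        raise ConfigError(f"unknown variable-selection method {method!r}")
    if method == "ga":
        return ga_select(X, y, config=GAConfig(**cfg), seed=seed)
    if method == "cars":
        return cars_select(X, y, seed=seed, **cfg)
    if method == "spa":
        return spa_select(X, y, **cfg)
    return sipls_select(X, y, **cfg)


def run_master_experiment(
    config: ExperimentConfig, batch=None, seed: int | None = None
) -> ExperimentReport:
    """Build the master model on the first (drift-free) batch.

    Stage 1 compares the preprocessing candidates on the full spectrum;
    stage 2 compares the configured wavelength-selection methods on the
    winning pretreatment.  The winner (lowest prediction-set RMSEP) is
    persisted in the returned report's ``master`` record.
    """
    seed = config.seed if seed is None else seed
    if batch is None:
        first = config.generator.batch_specs[0].name
        batch = synthdata.generate_batch(
            config.generator, first, seed=synthdata.batch_seeds(seed, 1)[0]
        )
    spectra, references = batch.spectra, batch.references

    rows = []
    stage1 = {}
    for p_spec in config.preprocess_candidates:
        row = {"stage": "preprocess", "method": p_spec.label, "failed": False}
        try:
            split, cal_p, y_cal, pred_p, y_pred, fitted_ref = _split_and_preprocess(
                spectra, references, p_spec, config.master_fraction, config.split_on
            )
            n = cal_p.n_wavelengths
            model, stats = _evaluate_subset(
                cal_p.absorbance, y_cal.values, pred_p.absorbance, y_pred.values,
                np.arange(n), config.max_lv,
            )
            row.update(stats)
            stage1[p_spec.label] = (p_spec, split, cal_p, y_cal, pred_p, y_pred,
                                    fitted_ref, model, stats)
        except NircalError as exc:
            row.update(failed=True, error=str(exc))
            logger.warning("preprocess candidate %s failed: %s", p_spec.label, exc)
        rows.append(row)

    if not stage1:
        raise NircalError("every preprocessing candidate failed")
    win_label = min(stage1, key=lambda k: stage1[k][8]["rmsep"])
    p_spec, split, cal_p, y_cal, pred_p, y_pred, fitted_ref, full_model, full_stats = stage1[
        win_label
    ]
    logger.info("winning pretreatment: %s (RMSEP %.3f)", win_label, full_stats["rmsep"])

    # the master model comes from the best wavelength-selection candidate
    # (parsimonious models transfer better); the full-spectrum model is kept
    # as the baseline row and used only if every selector fails
    best = None
    for i, method_cfg in enumerate(config.varsel_methods):
        label = method_cfg.get("method", "?")
        row = {"stage": "varsel", "method": label,
               "preprocess": win_label, "failed": False}
        try:
            sel = _run_selector(method_cfg, cal_p.absorbance, y_cal.values,
                                seed=seed + 1000 * (i + 1))
            model, stats = _evaluate_subset(
                cal_p.absorbance, y_cal.values, pred_p.absorbance, y_pred.values,
                sel.selected_indices, config.max_lv,
            )
            row.update(stats)
            if best is None or stats["rmsep"] < best[2]["rmsep"]:
                best = (label, model, stats)
        except NircalError as exc:
            row.update(failed=True, error=str(exc))
            logger.warning("varsel candidate %s failed: %s", label, exc)
        rows.append(row)
    if best is None:
        best = ("full", full_model, full_stats)

    master = MasterRecord(
        model=best[1],
        preprocess_spec=p_spec,
        msc_reference=fitted_ref,
        wavelengths=spectra.wavelengths,
        batch_label=spectra.batch_label,
        split=split,
        metrics={"varsel": best[0], **best[2]},
    )
    provenance = {"config_hash": config.config_hash(), "seed": seed,
                  "experiment": "master"}
    return ExperimentReport(rows=rows, provenance=provenance, master=master)


def _prepare_new_batch(master: MasterRecord, spectra, references, fraction, split_on):
    if spectra.wavelengths.shape != master.wavelengths.shape or not np.allclose(
        spectra.wavelengths, master.wavelengths
    ):
        raise AlignmentError(
            f"batch {spectra.batch_label!r} wavelength grid does not match the master model"
        )
    if split_on == "preprocessed":
        whole, _ = apply_preprocess(master.preprocess_spec, spectra,
                                    fitted_reference=master.msc_reference)
        split = kennard_stone_split(whole, fraction)
    else:
        split = kennard_stone_split(spectra, fraction)
    idx = master.model.wavelength_indices
    out = []
    for part in (split.calibration_indices, split.prediction_indices):
        s, _ = apply_preprocess(master.preprocess_spec, spectra.take(part),
                                fitted_reference=master.msc_reference)
        out.append(s.absorbance[:, idx])
    y_up = references.take(split.calibration_indices).values
    y_te = references.take(split.prediction_indices).values
    return out[0], y_up, out[1], y_te


def run_transfer_experiment(
    config: ExperimentConfig, master: MasterRecord, batches=None, seed: int | None = None
) -> ExperimentReport:
    """Direct vs independent-updated vs sequential-updated prediction per batch.

    ``batches`` is an ordered list of SyntheticBatch or (SpectraSet,
    ReferenceSet) pairs; by default the generator's later batches are drawn.
    Each batch is KS-split 40/60 into update/prediction sets on the master's
    preprocessing; updates run at ``config.rth``.
    """
    seed = config.seed if seed is None else seed
    if batches is None:
        batches = synthdata.generate_study(config.generator, seed=seed)[1:]
    if not batches:
        raise ConfigError("transfer experiment needs at least one new batch")

    prepared = []
    for b in batches:
        spectra, references = (
            (b.spectra, b.references) if hasattr(b, "spectra") else b
        )
        up_X, up_y, te_X, te_y = _prepare_new_batch(
            master, spectra, references, config.update_fraction, config.split_on
        )
        prepared.append((spectra.batch_label or f"batch{len(prepared) + 2}",
                         up_X, up_y, te_X, te_y))

    rows = []
    for scheme in ("independent", "sequential"):
        results = run_update_scheme(master.model, prepared, scheme=scheme, rth=config.rth)
        for res in results:
            if scheme == "independent":  # direct baseline identical across schemes
                rows.append({
                    "batch": res.batch_name, "method": "direct",
                    "rp": res.direct_metrics.r_as_printed,
                    "rp_pearson": res.direct_metrics.pearson_r,
                    "rmsep": res.direct_metrics.rmse,
                })
            rows.append({
                "batch": res.batch_name, "method": scheme,
                "rp": res.updated_metrics.r_as_printed,
                "rp_pearson": res.updated_metrics.pearson_r,
                "rmsep": res.updated_metrics.rmse,
                "constraint_value": res.updated_model.constraint_value,
                "objective": res.updated_model.objective,
                "converged": res.updated_model.converged,
            })
    rows.sort(key=lambda r: (r["batch"], ("direct", "independent", "sequential").index(r["method"])))
    provenance = {"config_hash": config.config_hash(), "seed": seed,
                  "experiment": "transfer", "rth": config.rth}
    return ExperimentReport(rows=rows, provenance=provenance, master=master)


def run_study(config: ExperimentConfig, seed: int | None = None):
    """Run both experiments end to end on one generated study.

    Returns ``(master_report, transfer_report)``; the same derived batch
    seeds feed both stages so the master batch is shared.
    """
    seed = config.seed if seed is None else seed
    study = synthdata.generate_study(config.generator, seed=seed)
    master_report = run_master_experiment(config, batch=study[0], seed=seed)
    transfer_report = run_transfer_experiment(
        config, master_report.master, batches=study[1:], seed=seed
    )
    return master_report, transfer_report
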