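"""Config-driven orchestration: preprocessing-candidate comparison, general
model fitting, T^2/Q diagnostics, optional VIP scan, and external-test
evaluation.

The workflow mirrors a standard chemometrics protocol: pool all varieties,
split calibration/validation per class, fit one PLS-DA model per
preprocessing candidate (latent variables selected by stratified k-fold CV on
the calibration set), compare candidates by validation accuracy, keep the
winner as the "general model", then screen new seed lots with the stored
chain and the ±0.5 rule.

All randomness flows from a single master seed split into named per-stage
streams (simulation, split, CV), so each stage is independently reproducible.
"""
from __future__ import annotations

import json
import logging
import time
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectraSet, read_spectra
from .errors import ConfigurationError, DataError
from .evaluation import EvalReport, confusion, evaluate, stratified_split
from .plsda import (PLSDAClassifier, classify_by_baseline, fit_nipals,
                    select_num_lvs)
from .preprocess import PreprocessChain
from .simulate import SimulationConfig, simulate_spectra
from .vip import VIPResult, threshold_scan

log = logging.getLogger("seednir")

ARCHIVE_FORMAT = "seednir-model/1"

DEFAULT_TRIM = (4000.0, 9000.0)

DEFAULT_CANDIDATES = (
    {"name": "raw", "trim": list(DEFAULT_TRIM), "steps": []},
    {"name": "sg1", "trim": list(DEFAULT_TRIM),
     "steps": [{"op": "savgol", "derivative_order": 1,
                "window_points": 9, "polyorder": 2}]},
)


@dataclass
class PipelineConfig:
    """Everything a training run needs; serializable as YAML."""

    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    load_path: str | None = None
    n_per_variety_per_class: int = 124
    candidates: list = field(
        default_factory=lambda: [deepcopy(c) for c in DEFAULT_CANDIDATES])
    validation_counts: int | None = 112
    validation_fraction: float | None = None
    max_lv: int = 12
    cv_folds: int = 10
    baseline: float = 0.5
    vip_scan: bool = False
    vip_thresholds: tuple = tuple(np.round(np.arange(0.8, 1.5001, 0.1), 10))
    diagnostics_confidence: float = 0.989
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not self.candidates:
            raise ConfigurationError("at least one preprocessing candidate required")

    def stage_seeds(self) -> dict:
        """Named per-stage integer seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {name: int(s >> 1)  # keep below 2**31
                for name, s in zip(("simulation", "split", "cv"), state)}

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "load_path": self.load_path,
            "n_per_variety_per_class": self.n_per_variety_per_class,
            "candidates": [deepcopy(c) for c in self.candidates],
            "validation_counts": self.validation_counts,
            "validation_fraction": self.validation_fraction,
            "max_lv": self.max_lv,
            "cv_folds": self.cv_folds,
            "baseline": self.baseline,
            "vip_scan": self.vip_scan,
            "vip_thresholds": [float(t) for t in self.vip_thresholds],
            "diagnostics_confidence": self.diagnostics_confidence,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if isinstance(sim, dict):
            for key in ("variety_baselines",):
                if key in sim:
                    sim[key] = {k: tuple(v) for k, v in sim[key].items()}
            for key in ("band_centers", "band_widths", "band_amplitudes_viable",
                        "band_amplitudes_nonviable", "discriminative_centers"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulate"] = SimulationConfig(**sim)
        if "vip_thresholds" in d:
            d["vip_thresholds"] = tuple(d["vip_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError("config document must be a mapping")
        try:
            return cls.from_dict(doc)
        except TypeError as exc:
            raise ConfigurationError(f"bad config field: {exc}") from None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------------
@dataclass
class GeneralModelResult:
    comparison: pd.DataFrame
    best_name: str
    model: PLSDAClassifier
    chain: PreprocessChain
    diagnostics: object
    archive: dict
    vip: VIPResult | None
    calibration: SpectraSet
    validation: SpectraSet
    seeds: dict


def _accuracy_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    cm = confusion(y_true, y_pred)
    return {
        "viable_correct": cm.tp, "viable_total": cm.tp + cm.fn,
        "nonviable_correct": cm.tn, "nonviable_total": cm.tn + cm.fp,
        "accuracy": (cm.tp + cm.tn) / cm.total,
    }


def _load_data(config: PipelineConfig, sim_seed: int) -> SpectraSet:
    if config.load_path is not None:
        data = read_spectra(config.load_path)
        if not data.is_labelled():
            raise DataError("training data contain 'unknown' labels")
        return data
    if config.simulate is None:
        raise ConfigurationError("config needs either a load_path or a "
                                 "simulation section")
    return simulate_spectra(config.simulate, config.n_per_variety_per_class,
                            seed=sim_seed)


def run_general_model(config: PipelineConfig) -> GeneralModelResult:
    """Fit and compare all preprocessing candidates; keep the best model."""
    seeds = config.stage_seeds()
    t0 = time.perf_counter()
    data = _load_data(config, seeds["simulation"])
    log.info("data: %d samples x %d wavenumbers", data.n_samples,
             data.n_wavenumbers)

    cal, val = stratified_split(
        data, validation_fraction=config.validation_fraction,
        validation_counts=config.validation_counts, seed=seeds["split"])
    log.info("split: calibration %d, validation %d (seed %d)",
             cal.n_samples, val.n_samples, seeds["split"])
    y_cal, y_val = cal.y(), val.y()

    rows, fitted = [], {}
    for cand in config.candidates:
        name = cand.get("name", "candidate")
        chain = PreprocessChain(steps=cand.get("steps"),
                                trim=cand.get("trim"), name=name)
        cal_p = chain.fit_apply(cal)
        val_p = chain.apply(val)
        a = select_num_lvs(cal_p.absorbance, y_cal, config.max_lv,
                           folds=config.cv_folds, seed=seeds["cv"],
                           baseline=config.baseline)
        model = fit_nipals(cal_p.absorbance, y_cal, a,
                           wavenumbers=cal_p.wavenumbers)
        model.baseline = config.baseline
        cal_pred, _ = classify_by_baseline(
            model.decision_function(cal_p.absorbance), config.baseline)
        val_pred, _ = classify_by_baseline(
            model.decision_function(val_p.absorbance), config.baseline)
        row = {"candidate": name, "n_lv": a}
        row.update({f"cal_{k}": v
                    for k, v in _accuracy_counts(y_cal, cal_pred).items()})
        row.update({f"val_{k}": v
                    for k, v in _accuracy_counts(y_val, val_pred).items()})
        rows.append(row)
        fitted[name] = (model, chain, cal_p)
        log.info("candidate %s: %d LVs, cal %.3f, val %.3f", name, a,
                 row["cal_accuracy"], row["val_accuracy"])

    comparison = pd.DataFrame(rows)
    order = comparison.sort_values(["val_accuracy", "n_lv"],
                                   ascending=[False, True], kind="stable")
    best_name = str(order.iloc[0]["candidate"])
    model, chain, cal_p = fitted[best_name]

    diag = model.diagnostics(cal_p.absorbance,
                             confidence=config.diagnostics_confidence)
    vip_result = None
    if config.vip_scan:
        vip_result = threshold_scan(
            cal_p.absorbance, y_cal, thresholds=config.vip_thresholds,
            max_lv=config.max_lv, folds=config.cv_folds, seed=seeds["cv"],
            baseline=config.baseline)

    archive = build_archive(model, chain, config, seeds, best_name)
    result = GeneralModelResult(
        comparison=comparison, best_name=best_name, model=model, chain=chain,
        diagnostics=diag, archive=archive, vip=vip_result,
        calibration=cal, validation=val, seeds=seeds)

    if config.output_dir is not None:
        _write_outputs(result, config)
    log.info("general model done in %.1f s (best: %s)",
             time.perf_counter() - t0, best_name)
    return result


def _write_outputs(result: GeneralModelResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(out / "comparison.csv", index=False)
    save_archive(result.archive, out / "model.json")
    d = result.diagnostics
    pd.DataFrame({
        "sample_id": result.calibration.sample_ids,
        "t2": d.t2, "q": d.q,
        "t2_flag": d.t2_flags, "q_flag": d.q_flags,
        "outlier": d.outlier_flags,
    }).to_csv(out / "diagnostics.csv", index=False)
    if result.vip is not None:
        pd.DataFrame(result.vip.scan_table,
                     columns=["threshold", "n_selected", "cv_accuracy"]
                     ).to_csv(out / "vip_scan.csv", index=False)


# ----------------------------------------------------------------------
# model archive
# ----------------------------------------------------------------------
def build_archive(model: PLSDAClassifier, chain: PreprocessChain,
                  config: PipelineConfig, seeds: dict, name: str) -> dict:
    """Serializable document sufficient for bit-reproducible prediction."""
    return {
        "format": ARCHIVE_FORMAT,
        "candidate": name,
        "class_code": {"nonviable": 0, "viable": 1},
        "baseline": model.baseline,
        "preprocess": chain.to_dict(),
        "n_lv": model.n_components_,
        "wavenumbers": model.wavenumbers_.tolist(),
        "x_mean": model.x_mean_.tolist(),
        "y_mean": model.y_mean_,
        "coef": model.coef_.tolist(),
        "x_weights": model.x_weights_.tolist(),
        "x_loadings": model.x_loadings_.tolist(),
        "y_loadings": model.y_loadings_.tolist(),
        "score_var": model.score_var_.tolist(),
        "residual_eigenvalues": model.residual_eigenvalues_.tolist(),
        "n_training_samples": model.n_samples_,
        "metadata": {
            "seeds": seeds,
            "cv_folds": config.cv_folds,
            "max_lv": config.max_lv,
            "diagnostics_confidence": config.diagnostics_confidence,
        },
    }


def save_archive(archive: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(archive, fh)


def load_archive(path) -> dict:
    with open(path) as fh:
        archive = json.load(fh)
    if archive.get("format") != ARCHIVE_FORMAT:
        raise ConfigurationError(
            f"unrecognized model archive format: {archive.get('format')!r}")
    return archive


def restore_model(archive: dict) -> tuple[PLSDAClassifier, PreprocessChain]:
    """Rebuild the fitted classifier and preprocessing chain from a document."""
    model = PLSDAClassifier(n_components=archive["n_lv"],
                            baseline=archive.get("baseline", 0.5))
    model.x_mean_ = np.asarray(archive["x_mean"], dtype=float)
    model.y_mean_ = float(archive["y_mean"])
    model.coef_ = np.asarray(archive["coef"], dtype=float)
    model.x_weights_ = np.asarray(archive["x_weights"], dtype=float)
    model.x_loadings_ = np.asarray(archive["x_loadings"], dtype=float)
    model.y_loadings_ = np.asarray(archive["y_loadings"], dtype=float)
    model.score_var_ = np.asarray(archive["score_var"], dtype=float)
    model.residual_eigenvalues_ = np.asarray(archive["residual_eigenvalues"],
                                             dtype=float)
    model.n_components_ = int(archive["n_lv"])
    model.n_training_samples_ = model.n_samples_ = int(
        archive["n_training_samples"])
    model.wavenumbers_ = np.asarray(archive["wavenumbers"], dtype=float)
    model.n_features_in_ = model.coef_.size
    model.classes_ = np.array([0, 1])
    chain = PreprocessChain.from_dict(archive["preprocess"])
    return model, chain


# ----------------------------------------------------------------------
# external test / prediction
# ----------------------------------------------------------------------
def _as_model_chain(model_or_archive):
    if isinstance(model_or_archive, dict):
        return restore_model(model_or_archive)
    if isinstance(model_or_archive, GeneralModelResult):
        return model_or_archive.model, model_or_archive.chain
    raise ConfigurationError("expected a model archive dict or a "
                             "GeneralModelResult")


def predict_lot(model_or_archive, sset: SpectraSet):
    """Apply the stored chain and model to new spectra.

    Returns (y_hat, labels, outside_baseline flags).
    """
    model, chain = _as_model_chain(model_or_archive)
    if sset.n_samples == 0:
        raise DataError("empty spectra set: nothing to predict")
    processed = chain.apply(sset)
    y_hat = model.decision_function(processed)
    labels, flags = classify_by_baseline(y_hat, model.baseline)
    return y_hat, labels, flags


def run_external_test(model_or_archive, test_set: SpectraSet,
                      seed: int | None = None) -> EvalReport:
    """Screen a labelled external lot and report Table-style metrics + ROC."""
    if test_set.n_samples == 0:
        raise DataError("empty test set")
    if not test_set.is_labelled():
        raise DataError("external test set must be fully labelled")
    y_hat, labels, _ = predict_lot(model_or_archive, test_set)
    return evaluate(test_set.y(), y_hat,
                    baseline=_as_model_chain(model_or_archive)[0].baseline,
                    seed=seed)
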