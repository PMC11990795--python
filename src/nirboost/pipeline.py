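"""End-to-end workflow: screen -> standardize -> split -> baselines ->
repeated UVE -> frequency tiers -> member models -> weighted ensemble.

``run_full`` produces a bundle holding every fitted artifact plus
calibration (cross-validated) and prediction-set evaluations for each model;
``report_table`` renders the comparison table (one row per model: raw,
z-score, single-run UVE, the three tier members and the ensemble).

Everything is reproducible from the single master seed; prediction-set rows
never enter standardization statistics, variable selection, latent-variable
choice or ensemble weighting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .dataio import SpectraSet
from .ensemble import EnsembleModel, adaboost_fit
from .errors import FitError
from .metrics import EvalReport, evaluate
from .plsr import CVResult, PLSModel, cross_validate, pls_fit, pls_predict
from .preprocess import (
    StandardizerState,
    robust_outlier_detect,
    zscore_apply,
    zscore_fit_transform,
)
from .sampling import SplitResult, split_dataset
from .uve import FrequencyProfile, UVEConfig, tier_partition, uve_repeat, uve_run

logger = logging.getLogger("nirboost")

__all__ = ["PipelineConfig", "ModelRecord", "PipelineBundle", "run_full",
           "report_table"]

MEMBER_ORDER = ("M1", "M2", "M3")  # high, mid, low frequency tiers


@dataclass
class PipelineConfig:
    significance: float = 0.95
    # 2 components for screening: the variance-based "auto" rule saturates on
    # noise-dominated spectra and over-flags
    outlier_k: int | str = 2
    screen_outliers: bool = True
    split_ratio: float = 0.7
    n_cal: Optional[int] = None
    uve: UVEConfig = field(default_factory=UVEConfig)
    adaboost_thresholds: Tuple[float, float] = (1.0, 1.5)
    max_lv: int = 15
    cv_folds: int = 5
    seed: int = 0


@dataclass
class ModelRecord:
    name: str
    model: PLSModel
    cv: CVResult
    cal_report: EvalReport
    pred_report: EvalReport
    n_variables: int


@dataclass
class PipelineBundle:
    config: PipelineConfig
    outlier_report: Optional[object]
    n_removed: int
    split: SplitResult
    standardizer: StandardizerState
    profile: FrequencyProfile
    models: Dict[str, ModelRecord]
    ensemble: Optional[EnsembleModel]
    ensemble_cal_report: Optional[EvalReport]
    ensemble_pred_report: Optional[EvalReport]


def _seeded(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _fit_and_score(
    name: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred_true: np.ndarray,
    variable_indices: np.ndarray,
    max_lv: int,
    k: int,
    seed: int,
) -> ModelRecord:
    cv = cross_validate(X_cal, y_cal, max_lv=max_lv, k=k, seed=seed)
    model = pls_fit(X_cal, y_cal, n_lv=cv.n_lv,
                    variable_indices=variable_indices)
    cal_rep = evaluate(y_cal, cv.oof_at_best, context="calibration_cv")
    pred = pls_predict(model, X_pred)
    pred_rep = evaluate(y_pred_true, pred, context="prediction")
    logger.info(
        "%s: %d variables, LV=%d, RMSECV=%.3f, RMSEP=%.3f",
        name, X_cal.shape[1], cv.n_lv, cal_rep.rmse, pred_rep.rmse,
    )
    return ModelRecord(
        name=name,
        model=model,
        cv=cv,
        cal_report=cal_rep,
        pred_report=pred_rep,
        n_variables=X_cal.shape[1],
    )


def run_full(ds: SpectraSet, config: Optional[PipelineConfig] = None) -> PipelineBundle:
    """Execute the whole calibration workflow on a dataset with a response."""
    if config is None:
        config = PipelineConfig()
    if ds.y is None:
        raise FitError("pipeline requires a response vector y")
    seeds = _seeded(config.seed, 10)

    # 1. robust outlier screen (flag-then-filter; never mutates the input)
    report = None
    n_removed = 0
    if config.screen_outliers:
        report = robust_outlier_detect(
            ds, k=config.outlier_k, significance=config.significance,
            seed=seeds[0],
        )
        keep = np.flatnonzero(~report.flags)
        n_removed = int(report.flags.sum())
        logger.info("outlier screen: removed %d of %d samples",
                    n_removed, ds.n_samples)
        ds = ds.subset(keep)

    # 2. Kennard-Stone split (distances on per-column standardized spectra)
    cal, pred, split = split_dataset(ds, ratio=config.split_ratio,
                                     n_cal=config.n_cal)
    logger.info("split: %d calibration / %d prediction",
                cal.n_samples, pred.n_samples)

    # 3. z-score fitted on the calibration set only
    X_cal_std, standardizer = zscore_fit_transform(cal.X)
    X_pred_std = zscore_apply(pred.X, standardizer)
    all_idx = np.arange(ds.n_wavelengths)

    models: Dict[str, ModelRecord] = {}
    models["raw"] = _fit_and_score(
        "raw", cal.X, cal.y, pred.X, pred.y, all_idx,
        config.max_lv, config.cv_folds, seeds[1],
    )
    models["zscore"] = _fit_and_score(
        "zscore", X_cal_std, cal.y, X_pred_std, pred.y, all_idx,
        config.max_lv, config.cv_folds, seeds[2],
    )

    # 4. single-run UVE baseline at the z-score model's optimal LV
    single = uve_run(X_cal_std, cal.y, config.uve, run_seed=seeds[3],
                     n_lv=models["zscore"].cv.n_lv)
    uve_idx = np.flatnonzero(single.selected)
    if uve_idx.size:
        models["uve"] = _fit_and_score(
            "uve", X_cal_std[:, uve_idx], cal.y, X_pred_std[:, uve_idx],
            pred.y, uve_idx, config.max_lv, config.cv_folds, seeds[4],
        )

    # 5. repeated UVE -> selection-frequency tiers
    _, profile = uve_repeat(X_cal_std, cal.y, config.uve,
                            n_lv=models["zscore"].cv.n_lv)
    tiers = tier_partition(profile)
    logger.info("tiers: high=%d, mid=%d, low=%d",
                *(t.size for t in tiers))

    members: list[PLSModel] = []
    member_oof: list[np.ndarray] = []
    for name, tier_idx, seed in zip(MEMBER_ORDER, tiers, seeds[5:8]):
        if tier_idx.size == 0:
            warnings.warn(f"tier for member {name} is empty; skipped",
                          stacklevel=2)
            continue
        rec = _fit_and_score(
            name, X_cal_std[:, tier_idx], cal.y, X_pred_std[:, tier_idx],
            pred.y, tier_idx, config.max_lv, config.cv_folds, seed,
        )
        models[name] = rec
        members.append(rec.model)
        member_oof.append(rec.cv.oof_at_best)

    # 6. AdaBoost weighting of the members (deviations from out-of-fold
    # calibration predictions, already computed above)
    ensemble = None
    ens_cal = ens_pred = None
    if members:
        ensemble = adaboost_fit(
            members, X_cal_std, cal.y,
            thresholds=config.adaboost_thresholds,
            member_predictions=member_oof,
            k=config.cv_folds, seed=seeds[8],
        )
        oof_combo = ensemble.weights @ np.stack(member_oof)
        ens_cal = evaluate(cal.y, oof_combo, context="calibration_cv")
        ens_pred = evaluate(pred.y, ensemble.predict(X_pred_std),
                            context="prediction")
        logger.info("ensemble weights: %s",
                    np.array2string(ensemble.weights, precision=4))

    return PipelineBundle(
        config=config,
        outlier_report=report,
        n_removed=n_removed,
        split=split,
        standardizer=standardizer,
        profile=profile,
        models=models,
        ensemble=ensemble,
        ensemble_cal_report=ens_cal,
        ensemble_pred_report=ens_pred,
    )


_ROW_LABELS = {
    "raw": "Raw spectra",
    "zscore": "z-score pretreatment",
    "uve": "Selected by UVE",
    "M1": "M1: high frequency",
    "M2": "M2: mid frequency",
    "M3": "M3: low frequency",
}


def report_table(bundle: PipelineBundle) -> pd.DataFrame:
    """One row per model with the standard column layout.

    Columns: Method, Variables, LV, RMSECV, Rcv, MAE_cal, RMSEP, Rp,
    MAE_pred, Bias. The ensemble row carries the member weights in a
    ``weights`` footnote column (blank elsewhere).
    """
    rows = []
    for key in ("raw", "zscore", "uve", "M1", "M2", "M3"):
        rec = bundle.models.get(key)
        if rec is None:
            continue
        rows.append({
            "Method": _ROW_LABELS[key],
            "Variables": rec.n_variables,
            "LV": rec.cv.n_lv,
            "RMSECV": rec.cal_report.rmse,
            "Rcv": rec.cal_report.r,
            "MAE_cal": rec.cal_report.mae,
            "RMSEP": rec.pred_report.rmse,
            "Rp": rec.pred_report.r,
            "MAE_pred": rec.pred_report.mae,
            "Bias": rec.pred_report.bias,
            "weights": "",
        })
    if bundle.ensemble is not None:
        rows.append({
            "Method": "AdaBoost ensemble",
            "Variables": "/",
            "LV": "/",
            "RMSECV": bundle.ensemble_cal_report.rmse,
            "Rcv": bundle.ensemble_cal_report.r,
            "MAE_cal": bundle.ensemble_cal_report.mae,
            "RMSEP": bundle.ensemble_pred_report.rmse,
            "Rp": bundle.ensemble_pred_report.r,
            "MAE_pred": bundle.ensemble_pred_report.mae,
            "Bias": bundle.ensemble_pred_report.bias,
            "weights": ",".join(f"{w:.4f}" for w in bundle.ensemble.weights),
        })
    return pd.DataFrame(rows)
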