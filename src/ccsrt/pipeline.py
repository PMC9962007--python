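"""End-to-end orchestration: train -> calibrate -> build database -> annotate.

Every stage records counts (exclusions, rejects, clipped predictions) in the
returned artifacts, and the run configuration is serialized alongside the
outputs with a content hash so any run is reproducible from its artifact
directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import annotator, calibration, ccs_cluster, db_builder, rt_qsrr, synthetic_data
from .chem_core import DEFAULT_ADDUCTS
from .errors import StageError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; every stochastic stage has an explicit seed."""

    out_dir: str = "ccsrt_run"
    seed: int = 0
    n_library: int = 200
    folds: int = 10
    n_clusters: int | None = 3
    adducts: tuple[str, ...] = DEFAULT_ADDUCTS
    run_length: float = synthetic_data.RUN_LENGTH
    mz_tol: float = 0.005
    tolerance_k: float = 2.0
    n_true: int = 40
    n_decoy: int = 30
    n_noise: int = 10
    holdout_fraction: float = 0.2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adducts"] = list(d["adducts"])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _split_indices(n: int, holdout_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_hold = int(round(holdout_fraction * n))
    return order[n_hold:], order[:n_hold]


def train_rt_stage(standards: pd.DataFrame, config: RunConfig) -> dict:
    """QSRR training on one Rt row per compound (mode-independent).

    Compounds observed with several adducts/modes contribute one Rt (the mean
    if replicates disagree). An 80/20 seeded split provides held-out
    validation; 10-fold CV runs on the training portion.
    """
    per_compound = (
        standards.groupby("id", as_index=False)
        .agg(smiles=("smiles", "first"), rt_min=("rt_min", "mean"),
             incomplete=("descriptor_incomplete", "max") if "descriptor_incomplete" in standards else ("rt_min", "size"))
    )
    rt_cfg = rt_qsrr.RtConfig(run_length=config.run_length)
    training = rt_qsrr.RtTrainingSet.from_records(
        per_compound["id"].tolist(), per_compound["smiles"].tolist(),
        per_compound["rt_min"].to_numpy(), run_length=config.run_length,
    )
    if "descriptor_incomplete" in standards.columns:
        flagged = set(per_compound.loc[per_compound["incomplete"].astype(bool), "id"])
        if flagged:  # NaN their descriptor rows so the filter excludes them
            keep = [i for i, cid in enumerate(training.ids) if cid not in flagged]
            dropped = [cid for cid in training.ids if cid in flagged]
            training = rt_qsrr.RtTrainingSet(
                ids=[training.ids[i] for i in keep],
                smiles=[training.smiles[i] for i in keep],
                rt=training.rt[keep],
                descriptor_matrix=training.descriptor_matrix[keep],
                descriptor_names=training.descriptor_names,
                excluded_ids=training.excluded_ids + dropped,
            )
            logger.info("excluded %d descriptor-incomplete compounds", len(dropped))
    tr_idx, ho_idx = _split_indices(len(training.ids), config.holdout_fraction, config.seed)
    train_set = rt_qsrr.RtTrainingSet(
        ids=[training.ids[i] for i in tr_idx],
        smiles=[training.smiles[i] for i in tr_idx],
        rt=training.rt[tr_idx],
        descriptor_matrix=training.descriptor_matrix[tr_idx],
        descriptor_names=training.descriptor_names,
        excluded_ids=training.excluded_ids,
    )
    model = rt_qsrr.fit_rt_model(train_set, rt_cfg, seed=config.seed)
    cv = rt_qsrr.cross_validate_rt(train_set, folds=config.folds, config=rt_cfg, seed=config.seed)
    model.cv_metrics = cv
    holdout = {}
    if len(ho_idx):
        Xh = training.descriptor_matrix[ho_idx][:, model.selected_indices]
        pred = model.pipeline.predict(Xh)
        obs = training.rt[ho_idx]
        err = pred - obs
        sst = float(np.sum((obs - obs.mean()) ** 2))
        holdout = {
            "mae": float(np.mean(np.abs(err))),
            "r2": 1.0 - float(np.sum(err**2)) / sst if sst > 0 else 1.0,
            "n": int(len(ho_idx)),
            "predicted": pred.tolist(),
            "measured": obs.tolist(),
        }
    return {"model": model, "cv": cv, "holdout": holdout, "training_set": train_set,
            "n_excluded": len(training.excluded_ids)}


def train_ccs_stage(standards: pd.DataFrame, config: RunConfig) -> dict:
    """Cluster-regression CCS training with a seeded held-out split."""
    ts = ccs_cluster.CcsTrainingSet.from_records(
        standards["id"].tolist(), standards["smiles"].tolist(),
        standards["adduct"].tolist(), standards["mz"].to_numpy(), standards["ccs_A2"].to_numpy(),
    )
    tr_idx, ho_idx = _split_indices(len(ts.ids), config.holdout_fraction, config.seed)
    sub = ccs_cluster.CcsTrainingSet(
        ids=[ts.ids[i] for i in tr_idx], smiles=[ts.smiles[i] for i in tr_idx],
        adducts=[ts.adducts[i] for i in tr_idx], mz=ts.mz[tr_idx], ccs=ts.ccs[tr_idx],
        descriptor_matrix=ts.descriptor_matrix[tr_idx], descriptor_names=ts.descriptor_names,
    )
    model = ccs_cluster.fit_ccs_model(sub, n_clusters=config.n_clusters, seed=config.seed)
    holdout = {}
    if len(ho_idx):
        preds = []
        for i in ho_idx:
            ccs, _ = ccs_cluster._predict_one(model, ts.descriptor_matrix[i], ts.mz[i], ts.adducts[i])
            preds.append(ccs)
        obs = ts.ccs[ho_idx]
        preds = np.asarray(preds)
        err = preds - obs
        sst = float(np.sum((obs - obs.mean()) ** 2))
        holdout = {
            "mae": float(np.mean(np.abs(err))),
            "r2": 1.0 - float(np.sum(err**2)) / sst if sst > 0 else 1.0,
            "n": int(len(ho_idx)),
            "predicted": preds.tolist(),
            "measured": obs.tolist(),
        }
    return {"model": model, "holdout": holdout, "training_set": sub, "n_excluded": len(ts.excluded_ids)}


def calibrate_stage(rt_result: dict, ccs_result: dict, config: RunConfig) -> dict:
    """Tolerance windows from held-out CCS residuals and Rt CV summaries."""
    ccs_cal = calibration.calibrate(
        ccs_result["holdout"]["predicted"], ccs_result["holdout"]["measured"],
        property="ccs", k=config.tolerance_k,
    )
    cv = rt_result["cv"]
    rt_tol = calibration.rt_tolerance_from_cv(cv["mean_mae"], cv["sd_mae"], k=config.tolerance_k)
    rt_cal = None
    if rt_result["holdout"]:
        rt_cal = calibration.calibrate(
            rt_result["holdout"]["predicted"], rt_result["holdout"]["measured"],
            property="rt", k=config.tolerance_k,
        )
    return {"ccs": ccs_cal, "rt_from_cv": {"tolerance": rt_tol, "mean_mae": cv["mean_mae"], "sd_mae": cv["sd_mae"]},
            "rt_holdout": rt_cal}


def run_pipeline(config: RunConfig) -> dict:
    """Synthetic-preset end-to-end run; returns all artifacts and writes a
    provenance-stamped summary under config.out_dir."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        library, truth = synthetic_data.generate_library(config.n_library, seed=config.seed)
        standards = synthetic_data.simulate_measurements(library, truth, seed=config.seed + 1)
        stage = "train-rt"
        rt_result = train_rt_stage(standards, config)
        stage = "train-ccs"
        ccs_result = train_ccs_stage(standards, config)
        stage = "calibrate"
        cal = calibrate_stage(rt_result, ccs_result, config)
        stage = "build-db"
        db, rejects = db_builder.build_database(
            library, ccs_result["model"], rt_result["model"], adducts=config.adducts
        )
        stage = "annotate"
        strategy1 = annotator.MatchStrategy(mz_tol=config.mz_tol)
        strategy2 = annotator.MatchStrategy(
            mz_tol=config.mz_tol, use_ccs=True, ccs_tol=cal["ccs"].tolerance,
            use_rt=True, rt_tol=cal["rt_from_cv"]["tolerance"],
        )
        features_df, db_aug, labels = synthetic_data.simulate_feature_table(
            db, truth, config.n_true, config.n_decoy, config.n_noise,
            seed=config.seed + 2, strategy=strategy2,
        )
        feats = [
            annotator.Feature(
                feature_id=r.feature_id, mz=r.mz, polarity=r.polarity,
                rt=r.rt_min, ccs=r.ccs_A2, intensity=r.intensity,
            )
            for r in features_df.itertuples()
        ]
        report1 = annotator.annotate_table(feats, db_aug, strategy1)
        report2 = annotator.annotate_table(feats, db_aug, strategy2)
        stats = annotator.hit_statistics(report1, report2)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    db_builder.write_database(db_aug, out / "database.csv")
    summary = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "counts": {
            "library": len(library),
            "standards_rows": len(standards),
            "rt_excluded": rt_result["n_excluded"],
            "ccs_excluded": ccs_result["n_excluded"],
            "db_rows": len(db),
            "db_rejects": len(rejects),
            "features": len(feats),
        },
        "rt": {"training": rt_result["model"].training_metrics, "cv": {k: v for k, v in rt_result["cv"].items() if k != "per_fold"},
               "holdout": {k: v for k, v in rt_result["holdout"].items() if k not in ("predicted", "measured")}},
        "ccs": {"training": ccs_result["model"].training_metrics,
                "holdout": {k: v for k, v in ccs_result["holdout"].items() if k not in ("predicted", "measured")}},
        "calibration": {"ccs": cal["ccs"].to_dict(), "rt_from_cv": cal["rt_from_cv"]},
        "annotation": stats,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {
        "library": library, "truth": truth, "standards": standards,
        "rt": rt_result, "ccs": ccs_result, "calibration": cal,
        "db": db_aug, "rejects": rejects, "features": feats, "labels": labels,
        "report_mz": report1, "report_full": report2, "stats": stats,
        "summary": summary,
    }
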