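"""QSRR retention-time model: descriptor filtering, SVR fitting, CV, prediction.

Retention time under a fixed reversed-phase gradient is modelled as a function
of 2D molecular descriptors (quantitative structure-retention relationship).
The reference regressor is an RBF-kernel support-vector machine tuned by a
seeded grid search; descriptors are filtered (missing values, near-zero
variance, pairwise correlation) and standardized before fitting. Retention
time is a property of the neutral molecule, so there is exactly one Rt per
compound regardless of adduct or ionization mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import chem_core
from .errors import (
    DegenerateInputError,
    FoldError,
    InsufficientDataError,
    PredictionUnavailable,
    StructureError,
)

logger = logging.getLogger(__name__)

#: Default hyperparameter grid for the RBF-kernel SVR. The smallest gamma
#: values make the kernel nearly linear, which matters when the retention
#: signal is a monotone function of a few descriptor directions diluted among
#: ~100 retained descriptors.
DEFAULT_SVR_GRID: dict[str, list] = {
    "svr__C": [1.0, 10.0, 100.0, 1000.0],
    "svr__gamma": [1e-4, 1e-3, 1e-2, "scale"],
    "svr__epsilon": [0.05, 0.1],
}

DEFAULT_VARIANCE_THRESHOLD = 1e-8
DEFAULT_CORRELATION_THRESHOLD = 0.95
MIN_TRAINING_COMPOUNDS = 20


@dataclass
class RtConfig:
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD
    svr_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SVR_GRID.items()})
    inner_cv_folds: int = 3
    run_length: float = 23.0  # chromatographic run length, min


@dataclass
class RtTrainingSet:
    """Compounds with one measured Rt each plus their descriptor matrix.

    ``excluded_ids`` lists compounds dropped for missing descriptors before
    modelling; they are reported, never silently discarded.
    """

    ids: list[str]
    smiles: list[str]
    rt: np.ndarray  # min
    descriptor_matrix: np.ndarray  # n_compounds x n_descriptors (may contain NaN)
    descriptor_names: list[str]
    excluded_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_records(cls, ids, smiles_list, rt_values, run_length: float = 23.0):
        """Build a training set, computing descriptors and excluding compounds
        whose structures fail or whose descriptors are incomplete."""
        rt_values = np.asarray(rt_values, dtype=float)
        mat, failed = chem_core.descriptor_matrix(list(smiles_list))
        keep, excluded = [], []
        for i in range(len(ids)):
            bad = i in failed or np.isnan(mat[i]).all() or not (0 <= rt_values[i] <= run_length)
            (excluded if bad else keep).append(i)
        if excluded:
            logger.info("excluded %d compounds (structure/descriptor/Rt-window)", len(excluded))
        return cls(
            ids=[str(ids[i]) for i in keep],
            smiles=[smiles_list[i] for i in keep],
            rt=rt_values[keep],
            descriptor_matrix=mat[keep],
            descriptor_names=list(chem_core.DESCRIPTOR_NAMES),
            excluded_ids=[str(ids[i]) for i in excluded],
        )


def filter_descriptors(
    matrix: np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> list[int]:
    """Descriptor pre-filter; returns retained column indices, in order.

    Drops, in order: columns with any missing value; columns with variance
    below ``variance_threshold``; then, for every pair with absolute Pearson
    correlation above ``correlation_threshold``, the later-indexed column.
    Deterministic for fixed input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise DegenerateInputError("empty descriptor matrix")
    n_cols = matrix.shape[1]
    retained = [j for j in range(n_cols) if not np.isnan(matrix[:, j]).any()]
    retained = [j for j in retained if np.var(matrix[:, j]) >= variance_threshold]
    if not retained:
        raise DegenerateInputError("all descriptors eliminated by the filter")
    sub = matrix[:, retained]
    corr = np.corrcoef(sub, rowvar=False)
    if corr.ndim == 0:  # single column
        return retained
    dropped = np.zeros(len(retained), dtype=bool)
    for a in range(len(retained)):
        if dropped[a]:
            continue
        for b in range(a + 1, len(retained)):
            if not dropped[b] and abs(corr[a, b]) > correlation_threshold:
                dropped[b] = True
    out = [retained[i] for i in range(len(retained)) if not dropped[i]]
    if not out:
        raise DegenerateInputError("all descriptors eliminated by the filter")
    return out


@dataclass
class RtModel:
    """Trained QSRR model artifact.

    Stores the fitted scaler+SVR pipeline, the retained descriptor panel, the
    per-descriptor training ranges (for extrapolation flagging), and metrics.
    """

    selected_descriptor_names: list[str]
    selected_indices: list[int]
    pipeline: Pipeline
    training_range: tuple[np.ndarray, np.ndarray]  # (min, max) per selected descriptor
    training_metrics: dict
    cv_metrics: dict | None
    run_length: float
    best_params: dict
    version: str = "1"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RtModel":
        return joblib.load(path)


def _make_pipeline(C=10.0, gamma="scale", epsilon=0.1) -> Pipeline:
    return Pipeline([("scaler", StandardScaler()), ("svr", SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon))])


def fit_rt_model(
    training: RtTrainingSet,
    config: RtConfig | None = None,
    seed: int = 0,
    _min_compounds: int = MIN_TRAINING_COMPOUNDS,
) -> RtModel:
    """Grid-searched SVR fit on the filtered, standardized descriptor panel.

    The grid search runs a seeded internal K-fold; the winning configuration
    is refit on the full training set. Training metrics (R², MAE in min) are
    apparent (in-sample) metrics; CV metrics come from cross_validate_rt.
    """
    config = config or RtConfig()
    if len(training.ids) < _min_compounds:
        raise InsufficientDataError(
            f"need >= {_min_compounds} compounds, got {len(training.ids)}"
        )
    sel = filter_descriptors(
        training.descriptor_matrix, config.variance_threshold, config.correlation_threshold
    )
    X = training.descriptor_matrix[:, sel]
    y = training.rt
    grid = config.svr_grid
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    if n_combos == 1:
        params = {k.split("__")[1]: v[0] for k, v in grid.items()}
        pipe = _make_pipeline(**params)
        pipe.fit(X, y)
        best_params = {k: v[0] for k, v in grid.items()}
    else:
        cv = KFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(_make_pipeline(), grid, cv=cv, scoring="neg_mean_absolute_error", n_jobs=1)
        search.fit(X, y)
        pipe = search.best_estimator_
        best_params = dict(search.best_params_)
    pred = pipe.predict(X)
    resid = pred - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    metrics = {"r2": r2, "mae": float(np.mean(np.abs(resid))), "n": len(y)}
    return RtModel(
        selected_descriptor_names=[training.descriptor_names[j] for j in sel],
        selected_indices=list(sel),
        pipeline=pipe,
        training_range=(X.min(axis=0), X.max(axis=0)),
        training_metrics=metrics,
        cv_metrics=None,
        run_length=config.run_length,
        best_params=best_params,
    )


def cross_validate_rt(
    training: RtTrainingSet, folds: int = 10, config: RtConfig | None = None, seed: int = 0
) -> dict:
    """K-fold CV of the full fitting procedure (filter + scale + grid inside
    each fold); returns {mean_r2, mean_mae, sd_mae, per_fold}.

    Rows are shuffled with the seed before splitting, so metrics do not depend
    on input row order. sd_mae is the n-1 SD of the per-fold MAE values.
    """
    config = config or RtConfig()
    n = len(training.ids)
    if folds < 2:
        raise FoldError("folds must be >= 2")
    if folds > n:
        raise FoldError(f"folds ({folds}) exceed number of compounds ({n})")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    # canonicalize by id before the seeded shuffle so fold composition does
    # not depend on input row order
    canonical = np.array(sorted(range(n), key=lambda i: training.ids[i]))
    order = canonical[np.random.default_rng(seed).permutation(n)]
    X_all = training.descriptor_matrix[order]
    y_all = training.rt[order]
    r2s, maes = [], []
    for train_idx, test_idx in kf.split(X_all):
        sub = RtTrainingSet(
            ids=[training.ids[order[i]] for i in train_idx],
            smiles=[training.smiles[order[i]] for i in train_idx],
            rt=y_all[train_idx],
            descriptor_matrix=X_all[train_idx],
            descriptor_names=training.descriptor_names,
        )
        # fold refits may dip below the final-model minimum (e.g. leave-one-out)
        model = fit_rt_model(sub, config, seed, _min_compounds=5)
        Xt = X_all[test_idx][:, model.selected_indices]
        pred = model.pipeline.predict(Xt)
        err = pred - y_all[test_idx]
        maes.append(float(np.mean(np.abs(err))))
        sst = float(np.sum((y_all[test_idx] - y_all[test_idx].mean()) ** 2))
        r2s.append(1.0 - float(np.sum(err**2)) / sst if sst > 0 else 1.0)
    return {
        "mean_r2": float(np.mean(r2s)),
        "mean_mae": float(np.mean(maes)),
        "sd_mae": float(np.std(maes, ddof=1)) if folds > 1 else 0.0,
        "per_fold": {"r2": r2s, "mae": maes},
        "folds": folds,
    }


def predict_rt(model: RtModel, smiles: str) -> tuple[float, bool]:
    """Predicted Rt (min) and an extrapolation flag.

    The flag is set when any selected descriptor lies outside its training
    range or the prediction falls outside the chromatographic window — both
    situations where QSRR predictions are known to be unreliable (unretained
    compounds, late eluters, chemistry unlike the training set).
    """
    try:
        dv = chem_core.compute_descriptors(smiles)
    except StructureError as exc:
        raise PredictionUnavailable(str(exc)) from exc
    name_to_pos = {n: i for i, n in enumerate(dv.names)}
    x = np.empty(len(model.selected_descriptor_names))
    for k, name in enumerate(model.selected_descriptor_names):
        pos = name_to_pos.get(name)
        if pos is None or dv.missing_mask[pos]:
            raise PredictionUnavailable(f"descriptor {name!r} incomputable for {smiles!r}")
        x[k] = dv.values[pos]
    lo, hi = model.training_range
    extrapolated = bool(np.any(x < lo) or np.any(x > hi))
    pred = float(model.pipeline.predict(x.reshape(1, -1))[0])
    if not (0.0 <= pred <= model.run_length):
        extrapolated = True
    return pred, extrapolated
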