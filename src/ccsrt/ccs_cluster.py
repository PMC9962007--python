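"""Cluster-based collision-cross-section prediction per (metabolite, adduct).

Architecture: compounds are partitioned in standardized descriptor space by
seeded k-means; one regressor per cluster maps (descriptors ⊕ m/z ⊕ one-hot
adduct) to CCS in Å². The adduct encoding carries both the mass shift (via
m/z) and the polarity, so positive and negative modes are modelled jointly
and two adducts of one metabolite get different predicted CCS. The default
per-cluster regressor is a grid-searched RBF SVR; ``kernel="linear"``
substitutes an ordinary least-squares fit.

The cluster count can be fixed or selected by mean silhouette over a range
(descriptor space only, so the choice reflects chemistry rather than the
adduct encoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression
from sklearn.metrics import silhouette_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import chem_core
from .chem_core import AdductSpec, MetaboliteRecord, adduct_mz, get_adduct
from .errors import AdductError, InsufficientDataError, PredictionUnavailable, StructureError
from .rt_qsrr import filter_descriptors

logger = logging.getLogger(__name__)

DEFAULT_CCS_SVR_GRID = {
    "C": [10.0, 100.0, 1000.0],
    "gamma": [1e-4, 1e-3, 1e-2],
    "epsilon": [0.1, 0.5],
}


@dataclass
class CcsConfig:
    kernel: str = "rbf"  # "rbf" (grid-searched SVR) or "linear" (OLS)
    svr_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CCS_SVR_GRID.items()})
    inner_cv_folds: int = 3
    min_cluster_size: int = 10
    k_range: tuple[int, int] = (2, 8)  # silhouette search range when n_clusters is None
    variance_threshold: float = 1e-8
    correlation_threshold: float = 0.95


@dataclass
class CcsTrainingSet:
    """(compound, adduct, measured CCS, m/z) entries plus descriptors.

    ``descriptor_matrix`` has one row per entry (compounds repeat across their
    adducts); each (metabolite, adduct) pair appears at most once.
    """

    ids: list[str]
    smiles: list[str]
    adducts: list[str]
    mz: np.ndarray
    ccs: np.ndarray  # Å²
    descriptor_matrix: np.ndarray
    descriptor_names: list[str]
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.ccs <= 0):
            raise ValueError("measured CCS must be positive")
        keys = list(zip(self.ids, self.adducts))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (metabolite, adduct) entries")

    @classmethod
    def from_records(cls, ids, smiles_list, adducts, mz, ccs):
        ids = list(ids)
        smiles_list = list(smiles_list)
        adducts = list(adducts)
        mz = np.asarray(mz, dtype=float)
        ccs = np.asarray(ccs, dtype=float)
        # one descriptor row per unique structure, broadcast to entries
        uniq: dict[str, np.ndarray | None] = {}
        for smi in smiles_list:
            if smi not in uniq:
                try:
                    dv = chem_core.compute_descriptors(smi)
                    uniq[smi] = dv.values
                except StructureError:
                    uniq[smi] = None
        keep, excluded = [], []
        for i, smi in enumerate(smiles_list):
            row = uniq[smi]
            (keep if row is not None and ccs[i] > 0 else excluded).append(i)
        mat = np.vstack([uniq[smiles_list[i]] for i in keep]) if keep else np.empty((0, 0))
        return cls(
            ids=[str(ids[i]) for i in keep],
            smiles=[smiles_list[i] for i in keep],
            adducts=[chem_core.normalize_adduct_label(adducts[i]) for i in keep],
            mz=mz[keep],
            ccs=ccs[keep],
            descriptor_matrix=mat,
            descriptor_names=list(chem_core.DESCRIPTOR_NAMES),
            excluded_ids=[str(ids[i]) for i in excluded],
        )


def _fit_regressor(X: np.ndarray, y: np.ndarray, config: CcsConfig, seed: int):
    if config.kernel == "linear":
        reg = LinearRegression()
        reg.fit(X, y)
        return reg
    grid = config.svr_grid
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    base = SVR(kernel="rbf")
    if n_combos == 1:
        base.set_params(**{k: v[0] for k, v in grid.items()})
        base.fit(X, y)
        return base
    n_splits = min(config.inner_cv_folds, len(y))
    if n_splits < 2:
        base.fit(X, y)
        return base
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, cv=cv, scoring="neg_mean_absolute_error", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


@dataclass
class CcsModel:
    """Trained cluster-regression CCS model artifact."""

    n_clusters: int
    kmeans: KMeans
    descriptor_scaler: StandardScaler
    feature_scaler: StandardScaler
    regressors: dict[int, object]  # cluster label -> fitted regressor
    selected_indices: list[int]
    selected_descriptor_names: list[str]
    adduct_labels: list[str]  # one-hot order
    cluster_counts: dict[int, int]
    cluster_max_dist: dict[int, float]
    training_metrics: dict
    version: str = "1"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CcsModel":
        return joblib.load(path)

    def _features(self, desc_sel: np.ndarray, mz: float, adduct_label: str) -> np.ndarray:
        onehot = np.zeros(len(self.adduct_labels))
        lab = chem_core.normalize_adduct_label(adduct_label)
        if lab not in self.adduct_labels:
            raise AdductError(f"adduct {adduct_label!r} not in model's supported set")
        onehot[self.adduct_labels.index(lab)] = 1.0
        return np.concatenate([desc_sel, [mz], onehot])


def select_n_clusters(descriptor_matrix: np.ndarray, config: CcsConfig | None = None, seed: int = 0) -> int:
    """Cluster count by mean silhouette over config.k_range on standardized,
    filtered descriptors."""
    config = config or CcsConfig()
    sel = filter_descriptors(descriptor_matrix, config.variance_threshold, config.correlation_threshold)
    X = StandardScaler().fit_transform(descriptor_matrix[:, sel])
    best_k, best_s = config.k_range[0], -np.inf
    for k in range(config.k_range[0], config.k_range[1] + 1):
        if k >= len(X):
            break
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def fit_ccs_model(
    training: CcsTrainingSet,
    n_clusters: int | None = 1,
    config: CcsConfig | None = None,
    seed: int = 0,
) -> CcsModel:
    """Cluster compounds, then fit one regressor per cluster.

    ``n_clusters=None`` selects k by silhouette. If any cluster falls below
    ``config.min_cluster_size`` the count is reduced automatically (logged);
    an error is raised only if even a single global cluster is too small.
    """
    config = config or CcsConfig()
    n = len(training.ids)
    if n_clusters is None:
        n_clusters = select_n_clusters(training.descriptor_matrix, config, seed)
    if n < 10 * n_clusters:
        n_clusters = max(1, n // 10)
        logger.info("reduced n_clusters to %d for %d entries", n_clusters, n)
    if n < config.min_cluster_size:
        raise InsufficientDataError(f"{n} entries < minimum cluster size {config.min_cluster_size}")
    sel = filter_descriptors(training.descriptor_matrix, config.variance_threshold, config.correlation_threshold)
    desc_scaler = StandardScaler().fit(training.descriptor_matrix[:, sel])
    D = desc_scaler.transform(training.descriptor_matrix[:, sel])

    while True:
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(D)
        counts = np.bincount(km.labels_, minlength=n_clusters)
        if counts.min() >= config.min_cluster_size or n_clusters == 1:
            break
        n_clusters -= 1
        logger.info("cluster below minimum occupancy; reducing n_clusters to %d", n_clusters)

    adduct_labels = sorted(set(training.adducts))
    onehot = np.zeros((n, len(adduct_labels)))
    for i, lab in enumerate(training.adducts):
        onehot[i, adduct_labels.index(lab)] = 1.0
    raw_feats = np.column_stack([training.descriptor_matrix[:, sel], training.mz, onehot])
    feat_scaler = StandardScaler().fit(raw_feats)
    F = feat_scaler.transform(raw_feats)

    regressors: dict[int, object] = {}
    for c in range(n_clusters):
        mask = km.labels_ == c
        regressors[c] = _fit_regressor(F[mask], training.ccs[mask], config, seed)
    dists = np.linalg.norm(D - km.cluster_centers_[km.labels_], axis=1)
    max_dist = {c: float(dists[km.labels_ == c].max()) for c in range(n_clusters)}

    pred = np.empty(n)
    for c in range(n_clusters):
        mask = km.labels_ == c
        pred[mask] = regressors[c].predict(F[mask])
    resid = pred - training.ccs
    sst = float(np.sum((training.ccs - training.ccs.mean()) ** 2))
    metrics = {
        "mae": float(np.mean(np.abs(resid))),
        "r2": 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0,
        "n": n,
    }
    return CcsModel(
        n_clusters=n_clusters,
        kmeans=km,
        descriptor_scaler=desc_scaler,
        feature_scaler=feat_scaler,
        regressors=regressors,
        selected_indices=list(sel),
        selected_descriptor_names=[training.descriptor_names[j] for j in sel],
        adduct_labels=adduct_labels,
        cluster_counts={c: int(counts[c]) for c in range(n_clusters)},
        cluster_max_dist=max_dist,
        training_metrics=metrics,
    )


def _predict_one(model: CcsModel, desc_values: np.ndarray, mz: float, adduct_label: str) -> tuple[float, bool]:
    desc_sel = desc_values[model.selected_indices]
    if np.isnan(desc_sel).any():
        raise PredictionUnavailable("selected descriptors incomputable for this structure")
    d_scaled = model.descriptor_scaler.transform(desc_sel.reshape(1, -1))
    dists = np.linalg.norm(model.kmeans.cluster_centers_ - d_scaled, axis=1)
    c = int(np.argmin(dists))
    flag = bool(dists[c] > model.cluster_max_dist[c])
    feats = model._features(desc_sel, mz, adduct_label).reshape(1, -1)
    ccs = float(model.regressors[c].predict(model.feature_scaler.transform(feats))[0])
    return ccs, flag


def predict_ccs(model: CcsModel, metabolite: MetaboliteRecord, adduct: AdductSpec | str) -> tuple[float, bool]:
    """Predicted CCS (Å²) for one (metabolite, adduct) plus extrapolation flag.

    The flag is set when the compound lies farther from its nearest cluster
    center than any training member of that cluster.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if adduct.label not in model.adduct_labels:
        raise AdductError(f"adduct {adduct.label!r} not supported by this model")
    try:
        dv = chem_core.compute_descriptors(metabolite.smiles)
    except StructureError as exc:
        raise PredictionUnavailable(str(exc)) from exc
    mz = adduct_mz(metabolite.neutral_mass, adduct)
    return _predict_one(model, dv.values, mz, adduct.label)


def batch_predict_ccs(
    model: CcsModel,
    metabolites: list[MetaboliteRecord],
    adduct_list: list[str],
    chunk_size: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted CCS for every (metabolite, applicable adduct) pair.

    Returns (predictions, rejects). Failed structures produce one reject row
    each and no prediction rows; memory stays bounded by processing compounds
    in chunks. An empty adduct list yields zero rows (warned).
    """
    if not adduct_list:
        logger.warning("empty adduct list: no predictions generated")
    adduct_specs = [get_adduct(a) for a in adduct_list]
    supported = [a for a in adduct_specs if a.label in model.adduct_labels]
    rows, rejects = [], []
    for start in range(0, len(metabolites), chunk_size):
        for met in metabolites[start : start + chunk_size]:
            try:
                if not met.usable:
                    raise StructureError(f"record {met.id} flagged unusable")
                dv = chem_core.compute_descriptors(met.smiles)
            except StructureError as exc:
                rejects.append({"metabolite_id": met.id, "reason": str(exc)})
                continue
            try:
                for add in supported:
                    mz = adduct_mz(met.neutral_mass, add)
                    ccs, flag = _predict_one(model, dv.values, mz, add.label)
                    rows.append(
                        {
                            "metabolite_id": met.id,
                            "adduct": add.label,
                            "polarity": add.polarity,
                            "mz": mz,
                            "ccs_pred_A2": ccs,
                            "extrapolation_flag": flag,
                        }
                    )
            except PredictionUnavailable as exc:
                rejects.append({"metabolite_id": met.id, "reason": str(exc)})
    pred_df = pd.DataFrame(
        rows, columns=["metabolite_id", "adduct", "polarity", "mz", "ccs_pred_A2", "extrapolation_flag"]
    )
    rej_df = pd.DataFrame(rejects, columns=["metabolite_id", "reason"])
    return pred_df, rej_df
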