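"""Feature-to-database matching under combined m/z + CCS + Rt tolerances.

Two strategies mirror common practice: strategy 1 matches on accurate mass
only (absolute m/z tolerance, default 5 mDa); strategy 2 additionally
requires the CCS and Rt of a candidate row to fall inside the calibrated
tolerance windows (defaults 16 Å² and 1.1 min). All window boundaries are
inclusive, polarity must always match, and hits are per (metabolite, adduct)
database row. Matching uses an m/z-sorted index with binary search; a naive
double-loop oracle lives in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CcsrtError

logger = logging.getLogger(__name__)


@dataclass
class Feature:
    """One untargeted LC-IMS-MS feature."""

    feature_id: str
    mz: float
    polarity: str
    rt: float
    ccs: float | None = None
    intensity: float = 0.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.rt < 0:
            raise ValueError("feature Rt must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass
class MatchStrategy:
    """Which dimensions participate in matching, with their tolerances.

    m/z always participates. ``missing_dimension`` controls what happens when
    a strategy requires CCS but the feature carries none: "pass" (default)
    ignores that dimension for the feature and flags it; "fail" yields no hit.
    """

    mz_tol: float = 0.005  # Th (absolute); 5 mDa default
    use_ccs: bool = False
    ccs_tol: float = 16.0  # Å²
    use_rt: bool = False
    rt_tol: float = 1.1  # min
    missing_dimension: str = "pass"
    mz_tol_ppm: float | None = None  # optional ppm mode; overrides mz_tol

    def __post_init__(self):
        if self.mz_tol <= 0 and self.mz_tol_ppm is None:
            raise ValueError("mz tolerance must be positive")
        if self.use_ccs and self.ccs_tol <= 0:
            raise ValueError("ccs tolerance must be positive")
        if self.use_rt and self.rt_tol <= 0:
            raise ValueError("rt tolerance must be positive")
        if self.missing_dimension not in ("pass", "fail"):
            raise ValueError("missing_dimension must be 'pass' or 'fail'")

    def mz_window(self, mz: float) -> float:
        if self.mz_tol_ppm is not None:
            return mz * self.mz_tol_ppm * 1e-6
        return self.mz_tol


#: Strategy 1 — accurate-mass match only.
STRATEGY_MZ = MatchStrategy()
#: Strategy 2 — accurate mass plus calibrated CCS and Rt windows.
STRATEGY_FULL = MatchStrategy(use_ccs=True, use_rt=True)

HIT_COLUMNS = [
    "feature_id", "metabolite_id", "adduct", "d_mz", "d_ccs", "d_rt",
    "score", "rank", "ccs_skipped",
]


@dataclass
class AnnotationReport:
    """Per-feature hits plus aggregate statistics for one strategy."""

    hits: pd.DataFrame  # HIT_COLUMNS
    n_features: int
    n_features_with_hits: int
    total_hits: int
    distribution: dict[str, int]  # bins "0", "1", "2-10", ">10"
    feature_ids: list[str] = field(default_factory=list)

    @property
    def aggregates(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_features_with_hits": self.n_features_with_hits,
            "total_hits": self.total_hits,
            "distribution": dict(self.distribution),
        }

    def per_metabolite(self) -> pd.DataFrame:
        """Collapsed view: one row per (feature, metabolite), best adduct hit.

        Several adducts of one metabolite may match one feature; gathering
        them supports cross-checking an identification across ion forms.
        """
        if self.hits.empty:
            return self.hits.iloc[0:0][["feature_id", "metabolite_id", "score"]]
        return (
            self.hits.sort_values("score", kind="mergesort")
            .groupby(["feature_id", "metabolite_id"], as_index=False)
            .first()[["feature_id", "metabolite_id", "adduct", "score"]]
        )


class _SortedDb:
    """m/z-sorted view of the database for binary-search candidate lookup."""

    def __init__(self, db: pd.DataFrame):
        self.db = db.reset_index(drop=True)
        order = np.argsort(self.db["mz"].to_numpy(), kind="mergesort")
        self.order = order
        self.sorted_mz = self.db["mz"].to_numpy()[order]

    def candidates(self, mz: float, tol: float) -> pd.DataFrame:
        lo = np.searchsorted(self.sorted_mz, mz - tol, side="left")
        hi = np.searchsorted(self.sorted_mz, mz + tol, side="right")
        return self.db.iloc[self.order[lo:hi]]


def _match_rows(feature: Feature, rows: pd.DataFrame, strategy: MatchStrategy) -> pd.DataFrame:
    tol = strategy.mz_window(feature.mz)
    d_mz = (rows["mz"] - feature.mz).abs()
    mask = (d_mz <= tol) & (rows["polarity"] == feature.polarity)
    ccs_skipped = False
    d_ccs = pd.Series(np.nan, index=rows.index)
    if strategy.use_ccs:
        if feature.ccs is None or (isinstance(feature.ccs, float) and math.isnan(feature.ccs)):
            if strategy.missing_dimension == "fail":
                mask &= False
            else:
                ccs_skipped = True
                logger.warning("feature %s lacks CCS; dimension skipped", feature.feature_id)
        else:
            d_ccs = (rows["ccs_A2"] - feature.ccs).abs()
            mask &= d_ccs <= strategy.ccs_tol
    d_rt = pd.Series(np.nan, index=rows.index)
    if strategy.use_rt:
        d_rt = (rows["rt_min"] - feature.rt).abs()
        mask &= d_rt <= strategy.rt_tol
    sel = rows[mask]
    out = pd.DataFrame(
        {
            "feature_id": feature.feature_id,
            "metabolite_id": sel["metabolite_id"].to_numpy(),
            "adduct": sel["adduct"].to_numpy(),
            "d_mz": d_mz[mask].to_numpy(),
            "d_ccs": d_ccs[mask].to_numpy(),
            "d_rt": d_rt[mask].to_numpy(),
            "ccs_skipped": ccs_skipped,
        }
    )
    return out


def _score_and_rank(hits: pd.DataFrame, strategy: MatchStrategy, feature_mz: float) -> pd.DataFrame:
    """Score = mean of normalized errors over enabled, usable dimensions;
    ascending rank with fully deterministic tie-breaking."""
    if hits.empty:
        hits = hits.copy()
        hits["score"] = pd.Series(dtype=float)
        hits["rank"] = pd.Series(dtype=int)
        return hits
    parts = [hits["d_mz"] / strategy.mz_window(feature_mz)]
    if strategy.use_ccs and hits["d_ccs"].notna().any():
        parts.append(hits["d_ccs"] / strategy.ccs_tol)
    if strategy.use_rt and hits["d_rt"].notna().any():
        parts.append(hits["d_rt"] / strategy.rt_tol)
    hits = hits.copy()
    hits["score"] = pd.concat(parts, axis=1).mean(axis=1)
    key = hits[["score", "d_mz", "d_ccs", "d_rt", "metabolite_id"]].copy()
    key["d_ccs"] = key["d_ccs"].fillna(0.0)
    key["d_rt"] = key["d_rt"].fillna(0.0)
    order = key.sort_values(
        ["score", "d_mz", "d_ccs", "d_rt", "metabolite_id"], kind="mergesort"
    ).index
    hits = hits.loc[order].reset_index(drop=True)
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits


def match_feature(feature: Feature, db: pd.DataFrame, strategy: MatchStrategy) -> pd.DataFrame:
    """Ranked hit list for one feature (columns HIT_COLUMNS).

    A db row is a hit iff |Δmz| <= mz_tol and, for each enabled dimension
    with a usable feature value, the absolute error is within its tolerance;
    boundaries inclusive, polarity must match.
    """
    sorted_db = db if isinstance(db, _SortedDb) else _SortedDb(db)
    rows = sorted_db.candidates(feature.mz, strategy.mz_window(feature.mz))
    hits = _match_rows(feature, rows, strategy)
    return _score_and_rank(hits, strategy, feature.mz)[HIT_COLUMNS]


def rank_candidates(hits: pd.DataFrame, strategy: MatchStrategy, feature_mz: float) -> pd.DataFrame:
    """Re-rank an unscored hit list (exposed for externally assembled hits)."""
    return _score_and_rank(hits.drop(columns=["score", "rank"], errors="ignore"), strategy, feature_mz)


def _bin_label(count: int) -> str:
    if count == 0:
        return "0"
    if count == 1:
        return "1"
    if count <= 10:
        return "2-10"
    return ">10"


def annotate_table(features: list[Feature], db: pd.DataFrame, strategy: MatchStrategy) -> AnnotationReport:
    """Match every feature and aggregate hit statistics.

    The hit-count distribution bins features into {0, 1, 2-10, >10} hits; the
    bins always sum to the number of features.
    """
    sorted_db = _SortedDb(db) if len(db) else None
    all_hits = []
    dist = {"0": 0, "1": 0, "2-10": 0, ">10": 0}
    n_with = 0
    total = 0
    for f in features:
        h = (
            match_feature(f, sorted_db, strategy)
            if sorted_db is not None
            else pd.DataFrame(columns=HIT_COLUMNS)
        )
        c = len(h)
        dist[_bin_label(c)] += 1
        if c:
            n_with += 1
            total += c
            all_hits.append(h)
    hits = pd.concat(all_hits, ignore_index=True) if all_hits else pd.DataFrame(columns=HIT_COLUMNS)
    return AnnotationReport(
        hits=hits,
        n_features=len(features),
        n_features_with_hits=n_with,
        total_hits=total,
        distribution=dist,
        feature_ids=[f.feature_id for f in features],
    )


def _pct(numer: int, denom: int) -> int:
    """Integer percent, truncated toward zero (46/51 -> 90, 37/51 -> 72);
    raw fractions are reported alongside."""
    if denom == 0:
        return 0
    return int(100.0 * numer / denom)


def hit_statistics(report_1: AnnotationReport, report_2: AnnotationReport) -> dict:
    """Compare a weaker and a stronger strategy over the same feature set.

    Returns integer percents (truncated) plus the raw fractions:
    percent of features with >= 1 hit under each strategy, percent of total
    hits removed by the stronger strategy, and the percentage-point change of
    the single-hit and >10-hit bins.
    """
    if report_1.n_features != report_2.n_features or set(report_1.feature_ids) != set(report_2.feature_ids):
        raise CcsrtError("hit_statistics requires reports over the same feature set")
    n = report_1.n_features
    pct1 = _pct(report_1.n_features_with_hits, n)
    pct2 = _pct(report_2.n_features_with_hits, n)
    filtered = (
        _pct(report_1.total_hits - report_2.total_hits, report_1.total_hits)
        if report_1.total_hits
        else 0
    )
    d_single = _pct(report_2.distribution["1"], n) - _pct(report_1.distribution["1"], n)
    d_gt10 = _pct(report_2.distribution[">10"], n) - _pct(report_1.distribution[">10"], n)
    return {
        "pct_features_with_hits_1": pct1,
        "pct_features_with_hits_2": pct2,
        "pct_hits_filtered": filtered,
        "delta_single_hit_pct": d_single,
        "delta_gt10_pct": d_gt10,
        "raw": {
            "frac_features_with_hits_1": report_1.n_features_with_hits / n if n else 0.0,
            "frac_features_with_hits_2": report_2.n_features_with_hits / n if n else 0.0,
            "frac_hits_filtered": (
                (report_1.total_hits - report_2.total_hits) / report_1.total_hits
                if report_1.total_hits
                else 0.0
            ),
        },
    }
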