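"""Feature matching, hit aggregation, strategy comparison, and ranking."""

import numpy as np
import pandas as pd
import pytest

from ccsrt.annotator import (
    STRATEGY_FULL,
    STRATEGY_MZ,
    AnnotationReport,
    Feature,
    MatchStrategy,
    annotate_table,
    hit_statistics,
    match_feature,
)
from ccsrt.errors import CcsrtError


def make_db(rows):
    cols = ["metabolite_id", "name", "formula", "adduct", "polarity",
            "mz", "ccs_A2", "rt_min", "ccs_flag", "rt_flag", "source"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = {"name": "", "formula": "", "adduct": "[M+H]+", "polarity": "positive",
                     "ccs_flag": False, "rt_flag": False, "source": "predicted"}.get(c, np.nan)
    return df[cols]


def double_loop_oracle(features, db, strategy):
    """Naive O(n*m) matching oracle."""
    hits = set()
    for f in features:
        for i, row in db.iterrows():
            if row["polarity"] != f.polarity:
                continue
            if abs(row["mz"] - f.mz) > strategy.mz_window(f.mz):
                continue
            if strategy.use_ccs and f.ccs is not None:
                if abs(row["ccs_A2"] - f.ccs) > strategy.ccs_tol:
                    continue
            if strategy.use_rt and abs(row["rt_min"] - f.rt) > strategy.rt_tol:
                continue
            hits.add((f.feature_id, row["metabolite_id"], row["adduct"]))
    return hits


def random_benchmark(rng, n_features=50, n_db=500):
    db = make_db(
        [
            {
                "metabolite_id": f"M{i}",
                "adduct": "[M+H]+" if i % 2 == 0 else "[M-H]-",
                "polarity": "positive" if i % 2 == 0 else "negative",
                "mz": rng.uniform(100, 600),
                "ccs_A2": rng.uniform(120, 260),
                "rt_min": rng.uniform(0.5, 17),
            }
            for i in range(n_db)
        ]
    )
    # half the features are placed near db rows so matches actually occur
    feats = []
    for j in range(n_features):
        if j % 2 == 0:
            row = db.iloc[int(rng.integers(n_db))]
            feats.append(
                Feature(f"F{j}", float(row["mz"] + rng.normal(0, 0.003)), row["polarity"],
                        float(max(0, row["rt_min"] + rng.normal(0, 0.5))),
                        float(row["ccs_A2"] + rng.normal(0, 8)), 1.0)
            )
        else:
            feats.append(
                Feature(f"F{j}", float(rng.uniform(100, 600)),
                        "positive" if rng.random() < 0.5 else "negative",
                        float(rng.uniform(0, 17)), float(rng.uniform(120, 260)), 1.0)
            )
    return feats, db


class TestMatchFeature:
    def test_exact_row_is_perfect_hit(self):
        db = make_db([{"metabolite_id": "M1", "mz": 180.0634, "ccs_A2": 140.0, "rt_min": 3.0}])
        f = Feature("F1", 180.0634, "positive", 3.0, 140.0)
        hits = match_feature(f, db, STRATEGY_FULL)
        assert len(hits) == 1
        assert hits.loc[0, "d_mz"] == 0 and hits.loc[0, "d_ccs"] == 0 and hits.loc[0, "d_rt"] == 0
        assert hits.loc[0, "score"] == 0

    def test_six_mda_misses_five_mda_window(self):
        db = make_db([{"metabolite_id": "M1", "mz": 300.0, "ccs_A2": 150.0, "rt_min": 5.0}])
        f = Feature("F1", 300.006, "positive", 5.0, 150.0)
        assert match_feature(f, db, STRATEGY_MZ).empty

    def test_boundary_is_inclusive(self):
        db = make_db([{"metabolite_id": "M1", "mz": 300.005, "ccs_A2": 150.0, "rt_min": 5.0}])
        f = Feature("F1", 300.000, "positive", 5.0, 150.0)
        assert len(match_feature(f, db, STRATEGY_MZ)) == 1

    def test_ccs_outside_window_passes_mz_only_strategy(self):
        """17 Å² off: hit on accurate mass alone, excluded by the combined
        m/z + CCS + Rt filter (16 Å² window)."""
        db = make_db([{"metabolite_id": "M1", "mz": 300.0, "ccs_A2": 150.0, "rt_min": 5.0}])
        f = Feature("F1", 300.0, "positive", 5.0, 167.0)
        assert len(match_feature(f, db, STRATEGY_MZ)) == 1
        assert match_feature(f, db, STRATEGY_FULL).empty

    def test_polarity_must_match(self):
        db = make_db([{"metabolite_id": "M1", "adduct": "[M-H]-", "polarity": "negative",
                       "mz": 300.0, "ccs_A2": 150.0, "rt_min": 5.0}])
        f = Feature("F1", 300.0, "positive", 5.0, 150.0)
        assert match_feature(f, db, STRATEGY_MZ).empty

    def test_missing_ccs_pass_policy_flags_and_keeps(self):
        db = make_db([{"metabolite_id": "M1", "mz": 300.0, "ccs_A2": 150.0, "rt_min": 5.0}])
        f = Feature("F1", 300.0, "positive", 5.0, ccs=None)
        hits = match_feature(f, db, STRATEGY_FULL)
        assert len(hits) == 1 and bool(hits.loc[0, "ccs_skipped"])
        strict = MatchStrategy(use_ccs=True, use_rt=True, missing_dimension="fail")
        assert match_feature(f, db, strict).empty

    def test_matches_double_loop_oracle(self, rng):
        feats, db = random_benchmark(rng)
        for strategy in (STRATEGY_MZ, STRATEGY_FULL):
            got = set()
            for f in feats:
                h = match_feature(f, db, strategy)
                got |= set(zip(h["feature_id"], h["metabolite_id"], h["adduct"]))
            assert got == double_loop_oracle(feats, db, strategy)

    def test_db_row_order_invariance(self, rng):
        feats, db = random_benchmark(rng, n_features=10, n_db=100)
        shuffled = db.sample(frac=1.0, random_state=0).reset_index(drop=True)
        for f in feats:
            a = match_feature(f, db, STRATEGY_FULL)
            b = match_feature(f, shuffled, STRATEGY_FULL)
            pd.testing.assert_frame_equal(a, b)


class TestStrategyMonotonicity:
    def test_stronger_strategy_hits_are_subset_per_feature(self, rng):
        feats, db = random_benchmark(rng)
        for f in feats:
            h1 = match_feature(f, db, STRATEGY_MZ)
            h2 = match_feature(f, db, STRATEGY_FULL)
            s1 = set(zip(h1["metabolite_id"], h1["adduct"]))
            s2 = set(zip(h2["metabolite_id"], h2["adduct"]))
            assert s2 <= s1

    def test_smaller_tolerance_hits_are_subset(self, rng):
        feats, db = random_benchmark(rng, n_features=20)
        wide = MatchStrategy(mz_tol=0.01)
        narrow = MatchStrategy(mz_tol=0.002)
        for f in feats:
            hw = set(match_feature(f, db, wide)["metabolite_id"])
            hn = set(match_feature(f, db, narrow)["metabolite_id"])
            assert hn <= hw


class TestAnnotateTable:
    def test_empty_feature_list(self, rng):
        _, db = random_benchmark(rng, n_features=2, n_db=20)
        report = annotate_table([], db, STRATEGY_MZ)
        assert report.n_features == 0 and report.total_hits == 0
        assert sum(report.distribution.values()) == 0

    def test_empty_db_gives_zero_hits(self):
        f = Feature("F1", 300.0, "positive", 5.0, 150.0)
        report = annotate_table([f], make_db([]).iloc[0:0], STRATEGY_MZ)
        assert report.total_hits == 0 and report.n_features_with_hits == 0

    def test_distribution_bins_conserve_feature_count(self, rng):
        feats, db = random_benchmark(rng)
        for strategy in (STRATEGY_MZ, STRATEGY_FULL):
            report = annotate_table(feats, db, strategy)
            assert sum(report.distribution.values()) == report.n_features == len(feats)
            assert report.total_hits == len(report.hits)
            assert report.n_features_with_hits <= report.n_features

    def test_feature_order_invariance(self, rng):
        feats, db = random_benchmark(rng, n_features=20, n_db=100)
        a = annotate_table(feats, db, STRATEGY_FULL)
        b = annotate_table(list(reversed(feats)), db, STRATEGY_FULL)
        assert a.total_hits == b.total_hits
        assert a.distribution == b.distribution
        ka = a.hits.sort_values(["feature_id", "metabolite_id", "adduct"]).reset_index(drop=True)
        kb = b.hits.sort_values(["feature_id", "metabolite_id", "adduct"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(ka, kb)


class TestRanking:
    def test_single_hit_gets_rank_one(self):
        db = make_db([{"metabolite_id": "M1", "mz": 300.0, "ccs_A2": 150.0, "rt_min": 5.0}])
        hits = match_feature(Feature("F1", 300.001, "positive", 5.0, 150.0), db, STRATEGY_FULL)
        assert list(hits["rank"]) == [1]

    def test_dominating_candidate_ranks_first(self):
        db = make_db([
            {"metabolite_id": "WORSE", "mz": 300.004, "ccs_A2": 158.0, "rt_min": 5.8},
            {"metabolite_id": "BETTER", "mz": 300.001, "ccs_A2": 151.0, "rt_min": 5.1},
        ])
        hits = match_feature(Feature("F1", 300.0, "positive", 5.0, 150.0), db, STRATEGY_FULL)
        assert list(hits["metabolite_id"]) == ["BETTER", "WORSE"]

    def test_tie_broken_by_candidate_id(self):
        db = make_db([
            {"metabolite_id": "MB", "mz": 300.002, "ccs_A2": 152.0, "rt_min": 5.2},
            {"metabolite_id": "MA", "mz": 300.002, "ccs_A2": 152.0, "rt_min": 5.2},
        ])
        hits = match_feature(Feature("F1", 300.0, "positive", 5.0, 150.0), db, STRATEGY_FULL)
        assert list(hits["metabolite_id"]) == ["MA", "MB"]


def report_with(n_features, with_hits, total, single=0, gt10=0):
    dist = {"0": n_features - with_hits, "1": single,
            "2-10": with_hits - single - gt10, ">10": gt10}
    return AnnotationReport(
        hits=pd.DataFrame(), n_features=n_features, n_features_with_hits=with_hits,
        total_hits=total, distribution=dist, feature_ids=[f"F{i}" for i in range(n_features)],
    )


class TestHitStatistics:
    def test_forty_six_of_fifty_one_is_ninety_percent(self):
        r1 = report_with(51, 46, 500, single=5, gt10=25)
        r2 = report_with(51, 37, 120, single=20, gt10=5)
        stats = hit_statistics(r1, r2)
        assert stats["pct_features_with_hits_1"] == 90
        assert stats["pct_features_with_hits_2"] == 72  # 37/51 truncates to 72

    def test_hundred_to_twenty_four_hits_is_76_percent_filtered(self):
        r1 = report_with(51, 46, 100)
        r2 = report_with(51, 37, 24)
        assert hit_statistics(r1, r2)["pct_hits_filtered"] == 76

    def test_identical_reports_give_zero_deltas(self):
        r = report_with(51, 46, 100, single=10, gt10=20)
        stats = hit_statistics(r, r)
        assert stats["pct_hits_filtered"] == 0
        assert stats["delta_single_hit_pct"] == 0
        assert stats["delta_gt10_pct"] == 0

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(CcsrtError):
            hit_statistics(report_with(51, 46, 100), report_with(50, 37, 24))
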