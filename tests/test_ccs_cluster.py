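"""Cluster-regression CCS model: fitting, prediction, batch runs."""

import numpy as np
import pandas as pd
import pytest

from ccsrt.ccs_cluster import (
    CcsConfig,
    CcsTrainingSet,
    batch_predict_ccs,
    fit_ccs_model,
    predict_ccs,
    select_n_clusters,
)
from ccsrt.chem_core import MetaboliteRecord
from ccsrt.errors import AdductError, PredictionUnavailable
from ccsrt.synthetic_data import generate_library, simulate_measurements


def make_synthetic_ccs_set(n=60, n_feats=5, noise=0.0, seed=0):
    """Direct-construction training set with a provided descriptor matrix."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_feats))
    mz = rng.uniform(100, 600, n)
    adducts = ["[M+H]+" if i % 2 == 0 else "[M-H]-" for i in range(n)]
    delta = np.array([2.0 if a == "[M+H]+" else -2.0 for a in adducts])
    ccs = 150 + 3 * X[:, 0] - 2 * X[:, 2] + 0.1 * mz + delta + rng.normal(0, noise, n)
    return CcsTrainingSet(
        ids=[f"c{i}" for i in range(n)],
        smiles=["CCO"] * n,
        adducts=adducts,
        mz=mz,
        ccs=ccs,
        descriptor_matrix=X,
        descriptor_names=[f"d{j}" for j in range(n_feats)],
    )


class TestOlsOracleEquivalence:
    def test_single_cluster_linear_kernel_matches_ols(self):
        """k = 1 with the linear regressor reproduces an ordinary
        least-squares oracle on the same features to 1e-6 relative."""
        ts = make_synthetic_ccs_set(noise=1.0)
        cfg = CcsConfig(kernel="linear")
        model = fit_ccs_model(ts, n_clusters=1, config=cfg, seed=0)
        # oracle: lstsq on raw (descriptors, mz, one-hot adduct) + intercept
        onehot = np.column_stack(
            [[1.0 if a == lab else 0.0 for a in ts.adducts] for lab in model.adduct_labels]
        )
        F = np.column_stack([ts.descriptor_matrix[:, model.selected_indices], ts.mz, onehot])
        A = np.column_stack([np.ones(len(ts.ids)), F])
        beta, *_ = np.linalg.lstsq(A, ts.ccs, rcond=None)
        oracle_pred = A @ beta
        got = np.array(
            [
                model.regressors[0].predict(
                    model.feature_scaler.transform(
                        model._features(ts.descriptor_matrix[i, model.selected_indices], ts.mz[i], ts.adducts[i]).reshape(1, -1)
                    )
                )[0]
                for i in range(len(ts.ids))
            ]
        )
        np.testing.assert_allclose(got, oracle_pred, rtol=1e-6)


class TestFitCcsModel:
    def test_single_cluster_is_global_regressor(self):
        ts = make_synthetic_ccs_set()
        model = fit_ccs_model(ts, n_clusters=1, config=CcsConfig(kernel="linear"), seed=0)
        assert model.n_clusters == 1
        assert set(model.cluster_counts.values()) == {len(ts.ids)}

    def test_determinism_same_seed(self, small_library):
        library, truth, measured = small_library
        ts = CcsTrainingSet.from_records(
            measured["id"], measured["smiles"].tolist(), measured["adduct"].tolist(),
            measured["mz"].to_numpy(), measured["ccs_A2"].to_numpy(),
        )
        cfg = CcsConfig(svr_grid={"C": [100.0], "gamma": [1e-3], "epsilon": [0.5]})
        m1 = fit_ccs_model(ts, n_clusters=2, config=cfg, seed=5)
        m2 = fit_ccs_model(ts, n_clusters=2, config=cfg, seed=5)
        np.testing.assert_array_equal(m1.kmeans.labels_, m2.kmeans.labels_)
        rec = library[0]
        assert predict_ccs(m1, rec, "[M+H]+")[0] == predict_ccs(m2, rec, "[M+H]+")[0]

    def test_cluster_occupancy_auto_reduction(self):
        ts = make_synthetic_ccs_set(n=25)
        model = fit_ccs_model(ts, n_clusters=8, config=CcsConfig(kernel="linear"), seed=0)
        assert model.n_clusters <= 2
        assert min(model.cluster_counts.values()) >= 10 or model.n_clusters == 1

    def test_generator_data_mae_within_noise_scale(self, study_run):
        """On square-root-mass synthetic CCS with 2 Å² noise, held-out MAE
        stays below 4 Å²."""
        assert study_run["ccs"]["holdout"]["mae"] <= 4.0
        assert study_run["ccs"]["holdout"]["n"] >= 80


class TestPredictCcs:
    def test_training_entry_predicted_near_measurement(self, study_run):
        model = study_run["ccs"]["model"]
        ts = study_run["ccs"]["training_set"]
        mae = model.training_metrics["mae"]
        errs = []
        for i in range(0, len(ts.ids), 40):
            got, _ = (
                __import__("ccsrt.ccs_cluster", fromlist=["_predict_one"])._predict_one(
                    model, ts.descriptor_matrix[i], ts.mz[i], ts.adducts[i]
                )
            )
            errs.append(abs(got - ts.ccs[i]))
        assert np.median(errs) <= max(2 * mae, 2.0)

    def test_adducts_of_one_metabolite_differ(self, study_run):
        model = study_run["ccs"]["model"]
        rec = study_run["library"][0]
        ccs_h, _ = predict_ccs(model, rec, "[M+H]+")
        ccs_na, _ = predict_ccs(model, rec, "[M+Na]+")
        assert ccs_h != ccs_na

    def test_far_outlier_is_flagged(self, study_run):
        model = study_run["ccs"]["model"]
        # a C60 fatty acid is far outside every training cluster
        rec = MetaboliteRecord.from_row("big", "giant acid", "C61H122O2", "C" * 60 + "C(=O)O")
        _, flag = predict_ccs(model, rec, "[M+H]+")
        assert flag

    def test_unsupported_adduct_raises(self, study_run):
        rec = study_run["library"][0]
        with pytest.raises(AdductError):
            predict_ccs(study_run["ccs"]["model"], rec, "[M+Cl]-" if "[M+Cl]-" not in study_run["ccs"]["model"].adduct_labels else "[2M+H]+")


class TestBatchPredict:
    def test_cardinality(self, study_run):
        model = study_run["ccs"]["model"]
        mets = study_run["library"][:10]
        adducts = model.adduct_labels[:4]
        pred, rej = batch_predict_ccs(model, mets, adducts)
        assert len(pred) == 10 * 4
        assert rej.empty

    def test_failed_structure_goes_to_rejects(self, study_run):
        model = study_run["ccs"]["model"]
        mets = list(study_run["library"][:4])
        bad = MetaboliteRecord.from_row("bad", "broken", "C6H12O6", "((((")
        pred, rej = batch_predict_ccs(model, mets + [bad], model.adduct_labels)
        assert len(pred) == 4 * len(model.adduct_labels)
        assert list(rej["metabolite_id"]) == ["bad"]

    def test_empty_adduct_list(self, study_run):
        pred, rej = batch_predict_ccs(study_run["ccs"]["model"], study_run["library"][:3], [])
        assert len(pred) == 0


class TestStructuralTrends:
    def test_monotone_mass_trend_within_homologous_series(self, study_run):
        """Predicted CCS is non-decreasing in neutral mass along a saturated
        fatty-acid series under one adduct."""
        model = study_run["ccs"]["model"]
        preds = []
        for n in range(8, 20, 2):
            smi = "C" * (n - 1) + "C(=O)O"
            formula = f"C{n}H{2 * n}O2"
            rec = MetaboliteRecord.from_row(f"fa{n}", f"FA {n}:0", formula, smi)
            ccs, _ = predict_ccs(model, rec, "[M+H]+")
            preds.append(ccs)
        diffs = np.diff(preds)
        assert np.all(diffs >= -0.5)  # non-decreasing up to regression wiggle
        assert preds[-1] > preds[0]

    def test_silhouette_recovers_three_separated_classes(self):
        """Cluster-count selection recovers k = 3 on a three-class descriptor
        mixture with class separation comparable to the generator's chemical
        families, for a majority of seeds."""
        hits = 0
        seeds = [11, 22, 33, 44, 55]
        for seed in seeds:
            rng = np.random.default_rng(seed)
            centers = rng.normal(0, 4.0, size=(3, 8))
            X = np.vstack([c + rng.normal(0, 1.0, size=(40, 8)) for c in centers])
            hits += select_n_clusters(X, seed=seed) == 3
        assert hits >= 3

    def test_generator_family_structure_drives_clustering(self):
        """On generator data, k-means at k = 3 in descriptor space aligns
        with the latent chemical families far better than chance."""
        from sklearn.metrics import adjusted_rand_score

        library, truth = generate_library(150, seed=11)
        measured = simulate_measurements(library, truth, seed=12)
        per_compound = measured.drop_duplicates("id")
        ts = CcsTrainingSet.from_records(
            per_compound["id"], per_compound["smiles"].tolist(),
            per_compound["adduct"].tolist(), per_compound["mz"].to_numpy(),
            per_compound["ccs_A2"].to_numpy(),
        )
        cfg = CcsConfig(svr_grid={"C": [100.0], "gamma": [1e-3], "epsilon": [0.5]})
        model = fit_ccs_model(ts, n_clusters=3, config=cfg, seed=11)
        families = [truth.classes[i] for i in ts.ids]
        ari = adjusted_rand_score(families, model.kmeans.labels_)
        assert ari > 0.2
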