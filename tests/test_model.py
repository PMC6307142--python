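"""Feature engineering, clustering, PCA subsetting and regression models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from riboquad import model

SMALL_GRID = {
    "n_estimators": [200],
    "max_depth": [2, 3],
    "learning_rate": [0.1],
    "min_samples_leaf": [5],
}


class TestZScoring:
    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 4)), columns=list("abcd"))
        once = model.zscore_columns(df)
        twice = model.zscore_columns(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())
        assert np.allclose(once.mean().to_numpy(), 0, atol=1e-9)
        assert np.allclose(once.std(ddof=0).to_numpy(), 1, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        assert (model.zscore_columns(df)["a"] == 0).all()


class TestClustering:
    def test_two_separated_blobs_recovered(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 0.05, (20, 3)), rng.normal(10, 0.05, (20, 3))]),
            columns=["te", "dg_ds", "dg_g4"],
        )
        labels = model.cluster_transcripts(X, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_planted_five_groups(self, rng):
        centers = np.array(
            [[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6], [6, 6, 6]], dtype=float
        )
        X = np.vstack([rng.normal(c, 0.3, (30, 3)) for c in centers])
        labels = model.cluster_transcripts(
            pd.DataFrame(X, columns=["te", "dg_ds", "dg_g4"]), k=5
        )
        truth = np.repeat(np.arange(5), 30)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_identical_points_deterministic(self):
        X = pd.DataFrame(np.zeros((6, 3)), columns=["te", "dg_ds", "dg_g4"])
        a = model.cluster_transcripts(X, k=2)
        b = model.cluster_transcripts(X, k=2)
        assert list(a) == list(b)

    def test_row_order_invariance(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, (15, 3)), rng.normal(5, 0.1, (15, 3))]),
            columns=["te", "dg_ds", "dg_g4"],
            index=[f"t{i}" for i in range(30)],
        )
        fwd = model.cluster_transcripts(X, k=2)
        rev = model.cluster_transcripts(X.iloc[::-1], k=2)
        assert (rev.reindex(fwd.index) == fwd).all()

    def test_k_larger_than_n_errors(self):
        X = pd.DataFrame(np.zeros((3, 3)), columns=["te", "dg_ds", "dg_g4"])
        with pytest.raises(ValueError):
            model.cluster_transcripts(X, k=5)


class TestPCA:
    def test_duplicated_features_load_jointly(self, rng):
        base = rng.normal(size=60)
        f = pd.DataFrame(
            {
                "dg_g4_per_nt": base,
                "dg_g4": base,  # perfect correlation
                "dg_ds_per_nt": rng.normal(size=60),
                "other": rng.normal(size=60),
            }
        )
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = model.pca_subset(f)
        assert res.variance_explained[0] >= 1.0 / f.shape[1]

    def test_sign_convention_fixed(self, rng):
        f = pd.DataFrame(
            rng.normal(size=(80, 5)),
            columns=["dg_g4_per_nt", "dg_ds_per_nt", "a", "b", "c"],
        )
        res = model.pca_subset(f)
        assert res.loadings.loc["dg_g4_per_nt", "Dim.1"] >= 0
        assert res.loadings.loc["dg_ds_per_nt", "Dim.2"] <= 0

    def test_rg4_subset_enriches_planted_transcripts(self, rng):
        n = 200
        planted = np.arange(n) < 60
        g4 = np.where(planted, rng.normal(2.0, 0.5, n), rng.normal(0, 0.5, n))
        f = pd.DataFrame(
            {
                "dg_g4_per_nt": g4,
                "dg_g4": g4 + rng.normal(0, 0.2, n),
                "dg_ds_per_nt": rng.normal(size=n),
                "len": rng.normal(size=n),
                "gc": rng.normal(size=n),
            }
        )
        res = model.pca_subset(f)
        sub = res.rg4_subset.to_numpy()
        table = [
            [int((planted & sub).sum()), int((planted & ~sub).sum())],
            [int((~planted & sub).sum()), int((~planted & ~sub).sum())],
        ]
        assert stats.fisher_exact(table)[1] < 0.01

    def test_too_small_input_errors(self):
        with pytest.raises(ValueError):
            model.pca_subset(pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]}))


class TestRegression:
    def test_linear_target_recovers_predictors(self, rng):
        n = 500
        X = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)]
        )
        y = 2 * X["f0"] - 1.5 * X["f1"] + X["f2"] + rng.normal(0, 0.05, n)
        report = model.fit_rpfdist_model(
            X, pd.Series(y), predictor_filter="all", seed=0, gbm_grid=SMALL_GRID
        )
        assert {"f0", "f1", "f2"} <= set(report.selected)
        assert report.r2_test > 0.9

    def test_pure_noise_target_has_no_skill(self, rng):
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
        y = rng.normal(size=n)
        report = model.fit_rpfdist_model(
            X, pd.Series(y), predictor_filter="all", seed=1, gbm_grid=SMALL_GRID
        )
        assert report.r2_test <= 0.05

    def test_empty_predictor_filter_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="empty predictor set"):
            model.fit_rpfdist_model(
                X,
                pd.Series(rng.normal(size=30)),
                categories={"a": "length", "b": "length"},
                predictor_filter="rG4",
            )

    def test_collinearity_screen_drops_redundant(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 200),
                          "c": rng.normal(size=200)})
        y = x + rng.normal(0, 0.1, 200)
        kept = model._collinearity_screen(X, y)
        assert "c" in kept
        assert not {"a", "b"} <= set(kept)  # one of the near-duplicates dropped


class TestCompareModels:
    def _report(self, values):
        return model.ModelReport(
            "x", [], 0, 0.0, [], 0.0, np.asarray(values, dtype=float), {}
        )

    def test_identical_resampling_gives_p_one(self):
        a = self._report(np.linspace(0, 1, 100))
        assert model.compare_models(a, a) == 1.0

    def test_disjoint_support_gives_tiny_p(self, rng):
        a = self._report(rng.uniform(0, 0.3, 100))
        b = self._report(rng.uniform(0.7, 1.0, 100))
        assert model.compare_models(a, b) < 1e-10

    def test_protocol_mismatch_errors(self):
        with pytest.raises(ValueError):
            model.compare_models(
                self._report(np.zeros(100)), self._report(np.zeros(50))
            )

    def test_same_distribution_p_uniformish(self, rng):
        ps = []
        for _ in range(30):
            a = self._report(rng.normal(size=60))
            b = self._report(rng.normal(size=60))
            ps.append(model.compare_models(a, b))
        assert 0.25 < np.mean(ps) < 0.75


class TestBuildFeatures:
    def test_feature_table_from_synthetic_cohort(self, default_sim):
        from riboquad import quant

        table = quant.translation_table(
            default_sim.annotations,
            default_sim.rpf_psites,
            default_sim.rna_coverage,
        )
        energies = pd.DataFrame(
            {
                "transcript_id": [a.transcript_id for a in default_sim.annotations],
                "dg_ds": np.linspace(-30, -5, len(default_sim.annotations)),
                "dg_g4": np.linspace(0, 20, len(default_sim.annotations)),
            }
        )
        feats, cats = model.build_features(
            default_sim.annotations, table, energies
        )
        assert len(feats) == len(default_sim.annotations)
        assert set(cats.values()) <= set(model.FEATURE_CATEGORIES)
        assert np.allclose(feats.mean().to_numpy(), 0, atol=1e-9)
        # every feature is categorized
        assert set(feats.columns) == set(cats)

    def test_cohort_mismatch_errors(self, default_sim):
        from riboquad import quant

        table = quant.translation_table(
            default_sim.annotations,
            default_sim.rpf_psites,
            default_sim.rna_coverage,
        )
        energies = pd.DataFrame(
            {"transcript_id": ["nope"], "dg_ds": [-1.0], "dg_g4": [0.0]}
        )
        with pytest.raises(ValueError, match="cohort mismatch"):
            model.build_features(default_sim.annotations, table, energies)
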