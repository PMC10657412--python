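"""PCA, gradient-boosted Cox layer, concordance, SHAP and perturbation."""

import numpy as np
import pandas as pd
import pytest

from tdnode.survival import (
    SurvivalDataset,
    assemble_features,
    concordance,
    concordance_from_risk,
    cross_validate_os,
    fit_os_model,
    km_vs_predicted_curves,
    pca_first_component,
    perturb_along_pc,
    shap_summary,
)


def _oracle_dataset(n=120, seed=0, noise=0.0, censor=None, spread=0.8):
    """Feature equals the negative log hazard; risk ordering is knowable."""
    rng = np.random.default_rng(seed)
    log_h = rng.normal(-4.0, spread, size=n)
    t = rng.exponential(1.0 / np.exp(log_h))
    e = np.ones(n, dtype=int)
    if censor is not None:
        e = (t <= censor).astype(int)
        t = np.minimum(t, censor)
    X = pd.DataFrame({"neg_log_hazard": -log_h + noise * rng.standard_normal(n)})
    return SurvivalDataset(X=X, time=t, event=e)


class TestPCA:
    def test_points_on_diagonal_line(self):
        x = np.linspace(-3, 3, 20)
        pc = pca_first_component(np.column_stack([x, x]) + 5.0)
        np.testing.assert_allclose(pc.loadings[0], [0.70710678, 0.70710678], atol=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(0)
        pc = pca_first_component(rng.standard_normal((50, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]]))
        np.testing.assert_allclose(pc.loadings @ pc.loadings.T, np.eye(2), atol=1e-10)

    def test_reconstruction_recovers_centered_data(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((30, 2)) * [3.0, 0.7] + [1.0, -2.0]
        pc = pca_first_component(data)
        recon = pc.scores @ pc.loadings + pc.mean
        np.testing.assert_allclose(recon, data, atol=1e-9)

    def test_scores_zero_mean_and_variance_shares_sum_to_one(self):
        rng = np.random.default_rng(2)
        pc = pca_first_component(rng.standard_normal((40, 2)))
        np.testing.assert_allclose(pc.scores.mean(axis=0), 0.0, atol=1e-10)
        assert pc.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError):
            pca_first_component(np.ones((10, 2)))


class TestConcordance:
    def test_perfect_anti_ordering_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_from_risk(risk, t, np.ones(4, int)) == 1.0

    def test_constant_risk_gives_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_from_risk(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10.0, size=50)
        risk = rng.standard_normal(50)
        e = np.ones(50, int)
        c = concordance_from_risk(risk, t, e)
        assert concordance_from_risk(-risk, t, e) == pytest.approx(1.0 - c, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10.0, size=200)
        e = np.ones(200, int)
        cs = [
            concordance_from_risk(np.random.default_rng(s).standard_normal(200), t, e)
            for s in range(20)
        ]
        assert abs(np.mean(cs) - 0.5) < 0.05


class TestOSModel:
    def test_oracle_feature_orders_training_risk(self):
        from scipy.stats import spearmanr

        data = _oracle_dataset(n=150, seed=0)
        model = fit_os_model(data)
        # the learned risk score recovers the true hazard ordering almost
        # perfectly (survival concordance itself is capped by the intrinsic
        # randomness of exponential event times)
        rho = spearmanr(model.predict_risk(data.X), -data.X["neg_log_hazard"]).statistic
        assert rho >= 0.85  # tree-leaf ties keep rank agreement just below 1
        assert concordance(model, data) >= 0.70

    def test_survival_curves_start_at_one(self):
        data = _oracle_dataset(n=80, seed=1, censor=60.0)
        model = fit_os_model(data)
        surv = model.predict_survival(data.X, np.array([0.0, 10.0, 50.0]))
        np.testing.assert_array_equal(surv[:, 0], 1.0)
        assert np.all(np.diff(surv, axis=1) <= 1e-12)

    def test_seeded_fit_reproducible(self):
        data = _oracle_dataset(n=60, seed=2, censor=80.0)
        r1 = fit_os_model(data).predict_risk(data.X)
        r2 = fit_os_model(data).predict_risk(data.X)
        np.testing.assert_array_equal(r1, r2)

    def test_all_censored_rejected(self):
        data = _oracle_dataset(n=30, seed=3)
        with pytest.raises(ValueError):
            fit_os_model(SurvivalDataset(data.X, data.time, np.zeros_like(data.event)))


class TestCrossValidation:
    def test_folds_partition_and_are_seeded(self):
        data = _oracle_dataset(n=100, seed=4, censor=100.0)
        a = cross_validate_os(data, k=5, seed=0)
        b = cross_validate_os(data, k=5, seed=0)
        all_test = np.concatenate([test for _, test in a["folds"]])
        assert sorted(all_test.tolist()) == list(range(100))
        assert all(len(test) == 20 for _, test in a["folds"])
        for (tr_a, te_a), (tr_b, te_b) in zip(a["folds"], b["folds"]):
            np.testing.assert_array_equal(te_a, te_b)

    def test_oracle_feature_generalizes(self):
        # wide hazard spread makes the outcome nearly deterministic in the
        # feature, so held-out concordance approaches 1
        data = _oracle_dataset(n=200, seed=5, spread=5.0)
        res = cross_validate_os(data, k=5, seed=0)
        assert res["median"] > 0.9


class TestShap:
    def test_local_additivity(self):
        data = _oracle_dataset(n=100, seed=6, censor=80.0)
        model = fit_os_model(data)
        shap = shap_summary(model, data.X)
        total = shap.drop(columns="base_value").sum(axis=1) + shap["base_value"]
        margin = model.predict_risk(data.X)
        assert np.max(np.abs(total.to_numpy() - margin)) <= 1e-6

    def test_exact_values_agree_with_library_treeshap(self):
        """The double-precision subset-enumeration Shapley values match the
        boosting library's TreeSHAP to its single-precision accuracy."""
        rng = np.random.default_rng(9)
        data = _oracle_dataset(n=120, seed=9, censor=80.0)
        X = data.X.copy()
        X["f2"] = rng.standard_normal(len(X))
        data2 = SurvivalDataset(X, data.time, data.event)
        model = fit_os_model(data2)
        exact = shap_summary(model, X).to_numpy()
        lib = model.booster.predict(model._dmatrix(X), pred_contribs=True)
        assert np.max(np.abs(exact - lib)) <= 5e-5

    def test_informative_feature_dominates_noise(self):
        rng = np.random.default_rng(7)
        data = _oracle_dataset(n=150, seed=7)
        X = data.X.copy()
        X["pure_noise"] = rng.standard_normal(len(X))
        data2 = SurvivalDataset(X, data.time, data.event)
        model = fit_os_model(data2)
        shap = shap_summary(model, X)
        assert shap["neg_log_hazard"].abs().mean() > shap["pure_noise"].abs().mean()


class TestAssembleFeatures:
    def _metrics(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "p1": rng.standard_normal(n),
                "p2": rng.standard_normal(n),
                "T": np.full(n, 30.0),
                "os_weeks": rng.exponential(60, n) + 1,
                "event": rng.integers(0, 2, n),
            }
        )

    @pytest.mark.parametrize(
        "fs,cols",
        [
            ("metrics", ["p1", "p2"]),
            ("pc1", ["pc1"]),
            ("pcs", ["pc1", "pc2"]),
        ],
    )
    def test_feature_sets_without_covariates(self, fs, cols):
        data = assemble_features(self._metrics(), fs)
        assert data.feature_names == cols

    def test_covariate_join(self):
        metrics = self._metrics(20)
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(20)], "age": np.arange(20.0)})
        data = assemble_features(metrics, "metrics+cov", cov)
        assert data.feature_names == ["p1", "p2", "age"]

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            assemble_features(self._metrics(), "everything")


class TestPerturbation:
    def test_delta_zero_matches_unperturbed(self, tiny_checkpoint):
        from tdnode.training import predict_profile

        ckpt, _, test_c, _ = tiny_checkpoint
        rec = test_c.records[0]
        fam = perturb_along_pc(
            ckpt, rec, np.array([0.70710678, 0.70710678]), n_perturb=5, n_times=20
        )
        direct = predict_profile(ckpt, rec, ckpt.config.window, fam["times_weeks"])
        np.testing.assert_allclose(fam["curves_mm"][0], direct, rtol=1e-7, atol=1e-8)

    def test_family_size_includes_original(self, tiny_checkpoint):
        ckpt, _, test_c, _ = tiny_checkpoint
        fam = perturb_along_pc(
            ckpt, test_c.records[1], np.array([1.0, 0.0]), n_perturb=11, n_times=10
        )
        assert fam["curves_mm"].shape == (12, 10)
        assert fam["deltas"][0] == 0.0

    def test_non_unit_loading_rejected(self, tiny_checkpoint):
        ckpt, _, test_c, _ = tiny_checkpoint
        with pytest.raises(ValueError):
            perturb_along_pc(ckpt, test_c.records[0], np.array([1.0, 1.0]))


class TestKMCurves:
    def test_km_starts_at_one_and_flat_without_events(self):
        data = _oracle_dataset(n=40, seed=8, censor=50.0)
        model = fit_os_model(data)
        arms = np.array(["a"] * 20 + ["b"] * 20)
        # arm b: all censored
        data2 = SurvivalDataset(
            data.X, data.time, np.where(arms == "b", 0, data.event)
        )
        out = km_vs_predicted_curves(model, data2, arms)
        for arm, res in out.items():
            assert res["km"][0] == 1.0
            assert res["pred_median"][0] == 1.0
        assert np.all(out["b"]["km"] == 1.0)
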