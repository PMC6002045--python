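import numpy as np
import pytest

from sdmrisk.evaluation import auc
from sdmrisk.maxent import (FeatureConfig, FeatureDef, FeatureSet, build_features,
                            fit_from_values, fit_maxent, jackknife, predict,
                            predict_scores, response_curve, training_gain,
                            variable_importance)
from _oracles import prox_gradient_maxent


def _random_values(rng, n, names):
    return {name: rng.normal(size=n) for name in names}


class TestBuildFeatures:
    def test_linear_quadratic_count(self):
        rng = np.random.default_rng(0)
        vals = _random_values(rng, 50, [f"v{i}" for i in range(6)])
        X, fs = build_features(vals, FeatureConfig("LQ"))
        assert X.shape == (50, 12)

    def test_product_count(self):
        rng = np.random.default_rng(0)
        vals = _random_values(rng, 50, [f"v{i}" for i in range(6)])
        X, fs = build_features(vals, FeatureConfig("LQP"))
        assert X.shape == (50, 27)  # 12 + C(6,2)

    def test_threshold_step_semantics(self):
        vals = {"x": np.linspace(0.0, 10.0, 101)}
        X, fs = build_features(vals, FeatureConfig("T", n_threshold_knots=1))
        knots = [d.knot for d in fs.defs]
        assert knots == [pytest.approx(5.0)]
        np.testing.assert_array_equal(X[:, 0], (vals["x"] > 5.0).astype(float))

    def test_features_scaled_to_unit_interval(self):
        rng = np.random.default_rng(1)
        vals = _random_values(rng, 80, ["a", "b"])
        X, _ = build_features(vals, FeatureConfig("LQPTH", n_hinge_knots=4,
                                                  n_threshold_knots=4))
        assert X.min() >= 0.0 and X.max() <= 1.0 + 1e-12

    def test_constant_variable_drops_knotted_features(self):
        vals = {"x": np.linspace(0, 1, 30), "k": np.full(30, 3.0)}
        with pytest.warns(UserWarning):
            X, fs = build_features(vals, FeatureConfig("LTH", n_hinge_knots=2,
                                                       n_threshold_knots=2))
        kinds = {(d.vars[0], d.kind) for d in fs.defs}
        assert ("k", "threshold") not in kinds and ("k", "hinge_fwd") not in kinds


class TestFit:
    def test_binary_feature_closed_form(self):
        # 50 of 100 background cells have f=1 and presence mean 0.8:
        # the moment condition 50 e^λ/(50 e^λ + 50) = 0.8 gives λ = ln 4
        X_bg = np.zeros((100, 1)); X_bg[:50, 0] = 1.0
        X_pres = np.zeros((10, 1)); X_pres[:8, 0] = 1.0
        fs = FeatureSet([FeatureDef("linear", ("x",))], {"x": (0.0, 1.0)},
                        np.zeros(1), np.ones(1))
        m = fit_maxent(X_pres, X_bg, fs, FeatureConfig("L"), betas=np.array([1e-9]))
        assert m.lambdas[0] == pytest.approx(np.log(4.0), abs=1e-4)

    def test_raw_distribution_normalized_over_background(self, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        pooled = {k: np.concatenate([vp[k], vb[k]]) for k in vb}
        assert m.raw(pooled).sum() == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_covariate_shrinks_to_chance(self):
        rng = np.random.default_rng(2)
        vp = {"noise": rng.normal(size=100)}
        vb = {"noise": rng.normal(size=400)}
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        scores_p = predict_scores(m, vp)
        scores_b = predict_scores(m, vb)
        assert abs(auc(scores_p, scores_b) - 0.5) < 0.08

    def test_objective_monotone_over_iterations(self, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        assert np.all(np.diff(m.objective_path) >= -1e-9)

    def test_oracle_equivalence_small_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n_bg = int(rng.integers(50, 200))
            names = ["a", "b", "c"][: int(rng.integers(2, 4))]
            vb = {k: rng.normal(size=n_bg) for k in names}
            shift = {k: rng.normal() for k in names}
            vp = {k: rng.normal(loc=shift[k], size=40) for k in names}
            cfg = FeatureConfig("LQ", rm=float(rng.choice([0.5, 1.0, 2.0])))
            m = fit_from_values(vp, vb, cfg)
            pooled = {k: np.concatenate([vp[k], vb[k]]) for k in names}
            X_all, fs = build_features(pooled, cfg)
            lam_oracle = prox_gradient_maxent(X_all[:40], X_all, m.betas)
            np.testing.assert_allclose(m.lambdas, lam_oracle, atol=1e-3)

    def test_rm_monotonicity_of_sparsity(self, small_training_data):
        vp, vb = small_training_data
        nnz = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            m = fit_from_values(vp, vb, FeatureConfig("LQH", rm=rm, n_hinge_knots=5))
            nnz.append(int((np.abs(m.lambdas) > 1e-5).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_scale_invariance_of_suitability(self, climate, truth_and_presences):
        _, _, occ = truth_and_presences
        rng = np.random.default_rng(4)
        cells = rng.integers(0, climate.shape[0], size=(800, 2))
        vb = {n: climate[n].values[cells[:, 0], cells[:, 1]] for n in ("bio1", "bio12")}
        vp_all = climate.values_at_points(occ.points)
        vp = {n: vp_all[n] for n in ("bio1", "bio12")}
        m1 = fit_from_values(vp, vb, FeatureConfig("LQ"))
        s1 = predict_scores(m1, vp)
        # affinely rescale bio1 everywhere (e.g. to Fahrenheit)
        vp2 = dict(vp); vb2 = dict(vb)
        vp2["bio1"] = vp["bio1"] * 1.8 + 32
        vb2["bio1"] = vb["bio1"] * 1.8 + 32
        m2 = fit_from_values(vp2, vb2, FeatureConfig("LQ"))
        s2 = predict_scores(m2, vp2)
        np.testing.assert_allclose(s1, s2, atol=1e-6)


class TestPredict:
    def test_output_in_unit_interval_and_modes_agree_in_envelope(
            self, climate, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        outs = {mode: predict(m, climate, clamp=mode) for mode in ("none", "clamp", "fade")}
        for s in outs.values():
            assert s.values.min() >= 0.0 and s.values.max() <= 1.0
        inside = outs["none"].clamp_counts == 0
        np.testing.assert_allclose(outs["none"].values[inside],
                                   outs["clamp"].values[inside], atol=1e-12)
        np.testing.assert_allclose(outs["none"].values[inside],
                                   outs["fade"].values[inside], atol=1e-12)

    def test_missing_variable_rejected(self, climate, small_training_data):
        vp, vb = small_training_data
        extra = {**vp, "absent": np.ones(len(next(iter(vp.values()))))}
        extra_b = {**vb, "absent": np.ones(len(next(iter(vb.values()))))}
        m = fit_from_values(extra, extra_b, FeatureConfig("L"))
        with pytest.raises(ValueError, match="absent"):
            predict(m, climate)


class TestImportance:
    def test_single_variable_model_gets_everything(self):
        rng = np.random.default_rng(5)
        vp = {"x": rng.normal(1.0, 1.0, 80)}
        vb = {"x": rng.normal(0.0, 1.0, 300)}
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        imp = variable_importance(m, vp, vb, seed=0)
        assert imp["x"]["percent_contribution"] == pytest.approx(100.0, abs=0.1)
        assert imp["x"]["permutation_importance"] == pytest.approx(100.0, abs=0.1)

    def test_contributions_sum_to_hundred(self, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        imp = variable_importance(m, vp, vb, seed=1)
        assert sum(v["percent_contribution"] for v in imp.values()) == pytest.approx(
            100.0, abs=0.1)

    def test_signal_variable_beats_noise(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vb = {"sig": rng.normal(size=300), "junk": rng.normal(size=300)}
            vp = {"sig": rng.normal(1.5, 0.7, 60), "junk": rng.normal(size=60)}
            m = fit_from_values(vp, vb, FeatureConfig("LQ"))
            imp = variable_importance(m, vp, vb, seed=seed)
            if imp["sig"]["permutation_importance"] > imp["junk"]["permutation_importance"]:
                wins += 1
        assert wins == 20


class TestJackknife:
    def test_fit_count_and_nesting(self, small_training_data):
        vp, vb = small_training_data
        names = list(vb)[:3]
        vp3 = {n: vp[n] for n in names}
        vb3 = {n: vb[n] for n in names}
        jk = jackknife(vp3, vb3, FeatureConfig("LQ"))
        assert len(jk["per_variable"]) == 3
        for rec in jk["per_variable"].values():
            assert rec["gain_with_only"] <= jk["full_gain"] + 1e-6

    def test_duplicated_variable_is_redundant(self, small_training_data):
        vp, vb = small_training_data
        vp2 = {"bio1": vp["bio1"], "copy": vp["bio1"].copy(), "bio12": vp["bio12"]}
        vb2 = {"bio1": vb["bio1"], "copy": vb["bio1"].copy(), "bio12": vb["bio12"]}
        jk = jackknife(vp2, vb2, FeatureConfig("LQ"))
        # dropping one copy leaves the other carrying the same information
        assert abs(jk["per_variable"]["copy"]["gain_without"] - jk["full_gain"]) < 1e-3


class TestResponseCurve:
    def test_outputs_in_unit_interval(self, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("LQ"))
        xs, ys = response_curve(m, "bio1", 50)
        assert len(xs) == 50 and ys.min() >= 0.0 and ys.max() <= 1.0

    def test_variable_with_no_features_gives_flat_curve(self):
        fs = FeatureSet([FeatureDef("linear", ("a",))],
                        {"a": (0.0, 1.0), "b": (0.0, 1.0)}, np.zeros(1), np.ones(1))
        from sdmrisk.maxent import MaxentModel
        m = MaxentModel(feature_set=fs, lambdas=np.array([1.0]),
                        betas=np.array([0.1]), rm=1.0, log_z=0.0, entropy=1.0,
                        presence_means={"a": 0.5, "b": 0.5}, n_presence=10,
                        n_background=100)
        xs, ys = response_curve(m, "b", 25)
        assert np.ptp(ys) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_variable_rejected(self, small_training_data):
        vp, vb = small_training_data
        m = fit_from_values(vp, vb, FeatureConfig("L"))
        with pytest.raises(ValueError, match="nope"):
            response_curve(m, "nope")
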