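import numpy as np
import pytest

from sdmrisk.synthetic import (TruthParams, make_climate, make_future,
                               sample_presences, true_suitability)


class TestMakeClimate:
    def test_deterministic_per_seed(self):
        a = make_climate(seed=5)
        b = make_climate(seed=5)
        for name in a.names:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_different_seeds_differ(self):
        a = make_climate(seed=5)
        b = make_climate(seed=6)
        assert not np.array_equal(a["bio1"].values, b["bio1"].values)

    def test_temperature_and_precipitation_ranges(self):
        s = make_climate(seed=0)
        t = s["bio1"].values
        p = s["bio12"].values
        assert t.min() >= -10 and t.max() <= 40
        assert p.min() >= 0 and p.max() <= 3000


class TestMakeFuture:
    def test_identity_perturbation(self, climate):
        fut = make_future(climate, delta_temp=0.0, precip_scale=1.0)
        for name in climate.names:
            np.testing.assert_array_equal(fut[name].values, climate[name].values)

    def test_temperature_shift_exact(self, climate):
        fut = make_future(climate, delta_temp=2.0, precip_scale=1.0)
        assert fut["bio1"].values.mean() - climate["bio1"].values.mean() == \
            pytest.approx(2.0, abs=1e-9)

    def test_precipitation_scaling_exact(self, climate):
        fut = make_future(climate, delta_temp=0.0, precip_scale=0.5)
        assert fut["bio12"].values.sum() == pytest.approx(
            climate["bio12"].values.sum() * 0.5)

    def test_noise_layers_untouched(self, climate):
        fut = make_future(climate, delta_temp=3.0, precip_scale=0.5)
        np.testing.assert_array_equal(fut["noise1"].values, climate["noise1"].values)


class TestTruth:
    def test_maximum_at_optimum_with_zero_precip(self, climate):
        params = TruthParams(temp_optimum=23.8, temp_sd=3.8, precip_halfsat=150.0)
        # analytic check on the functional form directly
        T = np.array([[23.8]]); P = np.array([[0.0]])
        s = np.exp(-((T - 23.8) ** 2) / (2 * 3.8 ** 2)) * 150.0 / (150.0 + P)
        assert s[0, 0] == 1.0

    def test_one_sd_from_optimum(self):
        from sdmrisk.grids import ClimateGrid, align_stack

        mask = np.zeros((1, 2), bool)
        T = ClimateGrid("bio1", [[23.8 + 3.8, 23.8 - 3.8]], mask, (0.0, 1.0), 1.0,
                        units="°C")
        P = ClimateGrid("bio12", [[0.0, 0.0]], mask, (0.0, 1.0), 1.0, units="mm")
        stack = align_stack([T, P])
        s = true_suitability(stack, TruthParams(temp_optimum=23.8, temp_sd=3.8))
        np.testing.assert_allclose(s.values, np.exp(-0.5), rtol=1e-12)

    def test_decreasing_in_precipitation(self, climate):
        params = TruthParams()
        s = true_suitability(climate, params)
        # same temperature, different precipitation: recompute with doubled P
        from sdmrisk.synthetic import make_future

        wetter = make_future(climate, delta_temp=0.0, precip_scale=2.0)
        s2 = true_suitability(wetter, params)
        drier_cells = climate["bio12"].values > 0
        assert (s2.values[drier_cells] < s.values[drier_cells]).all()


class TestSamplePresences:
    def test_concentrated_truth_hits_single_cell(self, climate):
        w = np.zeros(climate.shape)
        w[10, 20] = 1.0
        from sdmrisk.maxent import SuitabilityGrid

        truth = SuitabilityGrid(grid=climate.template.with_values(w),
                                transform="raw", clamp_mode="none",
                                clamp_counts=np.zeros(climate.shape, int))
        occ = sample_presences(truth, None, 50, seed=0)
        cells = {climate.template.cell_of(lon, lat) for lon, lat in occ.points}
        assert cells == {(10, 20)}

    def test_uniform_truth_chi_square(self):
        from scipy.stats import chi2
        from sdmrisk.grids import ClimateGrid
        from sdmrisk.maxent import SuitabilityGrid

        shape = (10, 10)
        g = ClimateGrid("t", np.ones(shape), np.zeros(shape, bool), (0.0, 5.0), 1.0)
        truth = SuitabilityGrid(grid=g, transform="raw", clamp_mode="none",
                                clamp_counts=np.zeros(shape, int))
        occ = sample_presences(truth, None, 10_000, seed=1)
        rows = np.array([g.cell_of(lon, lat) for lon, lat in occ.points])
        counts = np.bincount(rows[:, 0] * 10 + rows[:, 1], minlength=100)
        stat = ((counts - 100.0) ** 2 / 100.0).sum()
        assert stat < chi2.ppf(0.999, df=99)

    def test_deterministic_per_seed(self, truth_and_presences):
        _, truth, _ = truth_and_presences
        a = sample_presences(truth, None, 100, seed=3)
        b = sample_presences(truth, None, 100, seed=3)
        np.testing.assert_array_equal(a.points, b.points)


class TestWarmingShiftsSuitability:
    def test_mean_true_suitability_rises_under_warming(self):
        # optimum sits above the current mean temperature in most of the window
        agree = 0
        for seed in range(10):
            stack = make_climate(seed=seed)
            params = TruthParams()
            if params.temp_optimum <= stack["bio1"].values.mean():
                continue
            cur = true_suitability(stack, params).values.mean()
            fut = true_suitability(make_future(stack, delta_temp=2.0,
                                               precip_scale=1.0), params).values.mean()
            if fut > cur:
                agree += 1
        assert agree >= 9

    def test_fitted_projection_moves_with_the_truth(self):
        from sdmrisk.maxent import FeatureConfig, fit_from_values, predict

        agree = 0
        for seed in range(10):
            stack = make_climate(shape=(28, 28), seed=seed)
            params = TruthParams(n_presence=150, seed=seed)
            truth = true_suitability(stack, params)
            occ = sample_presences(truth, None, 150, seed=seed + 500)
            rng = np.random.default_rng(seed)
            cells = rng.integers(0, 28, size=(800, 2))
            vb = {n: stack[n].values[cells[:, 0], cells[:, 1]]
                  for n in ("bio1", "bio12")}
            vp_all = stack.values_at_points(occ.points)
            vp = {n: vp_all[n] for n in ("bio1", "bio12")}
            model = fit_from_values(vp, vb, FeatureConfig("LQ"))
            warmed = make_future(stack, delta_temp=2.0, precip_scale=1.0)
            truth_dir = (true_suitability(warmed, params).values.mean()
                         > truth.values.mean())
            model_dir = (predict(model, warmed, clamp="clamp").values.mean()
                         > predict(model, stack, clamp="clamp").values.mean())
            if truth_dir == model_dir:
                agree += 1
        assert agree >= 9
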