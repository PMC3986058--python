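import math

import numpy as np
import pytest

from socgeo import geostat
from socgeo.dataset_io import LocationGrid
from socgeo.errors import (
    DomainError,
    DuplicatePointsError,
    InsufficientDataError,
    NoPairsError,
)
from socgeo.geostat import (
    Semivariogram,
    VariogramModel,
    classify_dependence,
    directional_semivariogram,
    empirical_semivariogram,
    fit_model,
    krige,
    krige_map,
    loo_cross_validate,
    model_gamma,
    select_model,
)
from socgeo.synthetic_data import FieldParams, simulate_layer


def brute_force_semivariogram(coords, values, lag_width, max_dist):
    """All-pairs O(n^2) oracle with explicit loops."""
    n_bins = int(max_dist // lag_width)
    sums = [0.0] * n_bins
    dists = [0.0] * n_bins
    counts = [0] * n_bins
    n = len(values)
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(coords[i], coords[j])
            if d <= 0:
                continue
            for k in range(n_bins):
                if k * lag_width < d <= (k + 1) * lag_width:
                    sums[k] += (values[i] - values[j]) ** 2
                    dists[k] += d
                    counts[k] += 1
    gamma = [s / (2 * c) for s, c in zip(sums, counts) if c]
    lag = [d / c for d, c in zip(dists, counts) if c]
    npairs = [c for c in counts if c]
    return np.array(lag), np.array(gamma), np.array(npairs)


class TestEmpiricalSemivariogram:
    def test_two_points_single_pair(self):
        sv = empirical_semivariogram([[0, 0], [0, 400]], [1.0, 3.0],
                                     lag_width=500, max_dist=4700)
        assert len(sv.gamma) == 1
        assert sv.n_pairs[0] == 1
        assert sv.gamma[0] == pytest.approx(2.0)  # (3-1)^2 / 2
        assert sv.lag[0] == pytest.approx(400.0)

    def test_constant_field_is_zero(self, small_grid):
        sv = empirical_semivariogram(small_grid.coords(),
                                     np.full(small_grid.n_nodes, 7.0),
                                     lag_width=500, max_dist=1500)
        assert np.all(sv.gamma == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 3000, size=(40, 2))
        values = rng.normal(size=40)
        sv = empirical_semivariogram(coords, values, lag_width=500,
                                     max_dist=2500)
        lag, gamma, npairs = brute_force_semivariogram(
            coords.tolist(), values.tolist(), 500.0, 2500.0
        )
        np.testing.assert_allclose(sv.lag, lag, rtol=1e-12)
        np.testing.assert_allclose(sv.gamma, gamma, rtol=1e-12)
        np.testing.assert_array_equal(sv.n_pairs, npairs)

    def test_default_binning_gives_nine_bins(self, survey_grid, rng):
        values = rng.normal(size=survey_grid.n_nodes)
        sv = empirical_semivariogram(survey_grid.coords(), values)
        assert len(sv.gamma) == 9
        assert sv.bin_upper[-1] == 4500.0
        assert sv.n_pairs.sum() <= 187 * 186 / 2

    def test_coincident_points_rejected(self):
        with pytest.raises(NoPairsError):
            empirical_semivariogram([[0, 0], [0, 0]], [1.0, 2.0])


class TestDirectionalSemivariogram:
    def test_full_tolerance_equals_omnidirectional(self, small_grid, rng):
        values = rng.normal(size=small_grid.n_nodes)
        omni = empirical_semivariogram(small_grid.coords(), values,
                                       lag_width=500, max_dist=1500)
        direc = directional_semivariogram(small_grid.coords(), values, 37.0,
                                          tolerance_deg=90.0, lag_width=500,
                                          max_dist=1500)
        np.testing.assert_allclose(direc.gamma, omni.gamma)
        np.testing.assert_array_equal(direc.n_pairs, omni.n_pairs)

    def test_east_west_trend_is_anisotropic(self, survey_grid, rng):
        coords = survey_grid.coords()
        # pure E-W gradient + small noise: E-W variogram grows as (slope h)^2/2
        values = 1e-3 * coords[:, 0] + rng.normal(0, 0.05, len(coords))
        ew = directional_semivariogram(coords, values, azimuth_deg=90.0,
                                       tolerance_deg=20.0)
        ns = directional_semivariogram(coords, values, azimuth_deg=0.0,
                                       tolerance_deg=20.0)
        assert ew.gamma[-1] > 10 * ns.gamma.max()
        expected = (1e-3 * ew.lag[-1]) ** 2 / 2
        assert ew.gamma[-1] == pytest.approx(expected, rel=0.2)

    def test_empty_cone_rejected(self):
        coords = [[0, 0], [0, 1000]]  # N-S pair only
        with pytest.raises(NoPairsError):
            directional_semivariogram(coords, [0.0, 1.0], azimuth_deg=90.0,
                                      tolerance_deg=5.0)


class TestModelGamma:
    def test_exponential_asymptote_and_worked_value(self):
        m = VariogramModel("exponential", nugget=0.0019, sill=0.1048,
                           range_m=1347.0)
        assert m.gamma(1e9) == pytest.approx(0.1048, rel=1e-6)
        # at the effective range: C0 + C * (1 - e^-3)
        assert m.gamma(1347.0) == pytest.approx(
            0.0019 + 0.1029 * (1 - math.exp(-3)), rel=1e-12
        )
        assert m.gamma(1347.0) == pytest.approx(0.0997, abs=5e-4)

    def test_spherical_reaches_sill_exactly_at_range(self):
        m = VariogramModel("spherical", nugget=0.1, sill=1.1, range_m=800.0)
        assert m.gamma(800.0) == pytest.approx(1.1, rel=1e-14)
        assert m.gamma(5000.0) == 1.1

    def test_gamma_at_zero_is_zero(self):
        for family in ("exponential", "spherical", "gaussian", "linear"):
            m = VariogramModel(family, nugget=0.2, sill=1.0, range_m=500.0,
                               slope=1e-3)
            assert m.gamma(0.0) == 0.0
            assert m.gamma(1e-9) > 0.19  # nugget is a limit from the right

    def test_negative_lag_rejected(self):
        m = VariogramModel("exponential", 0.0, 1.0, 100.0)
        with pytest.raises(DomainError):
            model_gamma(m, -1.0)

    def test_effective_range_to_raw_parameter(self):
        exp = VariogramModel("exponential", 0.0, 1.0, 900.0)
        gau = VariogramModel("gaussian", 0.0, 1.0, 900.0)
        assert exp.range_parameter == pytest.approx(300.0)
        assert gau.range_parameter == pytest.approx(900.0 / math.sqrt(3))


class TestClassifyDependence:
    @pytest.mark.parametrize(
        "ratio,label",
        [(0.018, "strong"), (0.054, "strong"), (0.24999, "strong"),
         (0.25, "moderate"), (0.5, "moderate"), (0.75, "moderate"),
         (0.7501, "weak"), (0.9, "weak")],
    )
    def test_thresholds(self, ratio, label):
        assert classify_dependence(ratio) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            classify_dependence(1.2)


def _synthetic_sv(model, lags, npairs=None, jitter=None, rng=None):
    gamma = model.gamma(lags)
    if jitter is not None:
        gamma = gamma * np.exp(rng.normal(0, jitter, lags.size))
    npairs = npairs if npairs is not None else np.full(lags.size, 100)
    return Semivariogram(
        lag=lags, gamma=gamma, n_pairs=np.asarray(npairs),
        bin_upper=lags + 250.0, lag_width=500.0, max_dist=float(lags.max() + 250),
        scale="ln",
    )


def grid_search_rss(sv, family, n_grid=60):
    """Dense-grid WLS oracle over (C0, C, A)."""
    w = sv.n_pairs.astype(float)
    gmax = sv.gamma.max()
    best = np.inf
    for a in np.linspace(50.0, 2 * sv.max_dist, n_grid):
        for c0 in np.linspace(0, 1.2 * gmax, n_grid):
            for c in np.linspace(0, 2.0 * gmax, n_grid):
                m = VariogramModel(family, nugget=c0, sill=c0 + c, range_m=a)
                rss = float((w * (sv.gamma - m.gamma(sv.lag)) ** 2).sum())
                best = min(best, rss)
    return best


class TestFitModel:
    lags = np.arange(250.0, 4700.0, 500.0)

    @pytest.mark.parametrize("family", ["exponential", "spherical", "gaussian"])
    def test_noiseless_recovery(self, family):
        truth = VariogramModel(family, nugget=0.02, sill=0.13, range_m=1300.0)
        fit = fit_model(_synthetic_sv(truth, self.lags), family)
        assert fit.nugget == pytest.approx(0.02, abs=1e-6)
        assert fit.sill == pytest.approx(0.13, abs=1e-6)
        assert fit.range_m == pytest.approx(1300.0, rel=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_linear_recovery(self):
        truth = VariogramModel("linear", nugget=0.01, sill=0.01,
                               range_m=4000.0, slope=2e-5)
        fit = fit_model(_synthetic_sv(truth, self.lags), "linear")
        assert fit.nugget == pytest.approx(0.01, abs=1e-9)
        assert fit.slope == pytest.approx(2e-5, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = VariogramModel("exponential", nugget=0.01 * rng.uniform(0, 3),
                               sill=0.1 * rng.uniform(0.8, 1.5),
                               range_m=rng.uniform(600, 2500))
        sv = _synthetic_sv(truth, self.lags, jitter=0.1, rng=rng,
                           npairs=rng.integers(50, 500, self.lags.size))
        fit = fit_model(sv, "exponential")
        oracle = grid_search_rss(sv, "exponential")
        assert fit.rss <= oracle * 1.01

    def test_pair_count_weights_matter(self):
        truth = VariogramModel("exponential", 0.0, 0.1, 1200.0)
        gamma = truth.gamma(self.lags).copy()
        gamma[-1] *= 3.0  # corrupt the last bin
        sv_low = Semivariogram(self.lags, gamma, np.array([500] * 8 + [1]),
                               self.lags + 250, 500.0, 4700.0)
        fit = fit_model(sv_low, "exponential")
        # the corrupted bin carries almost no weight
        assert fit.sill == pytest.approx(0.1, rel=0.05)

    def test_too_few_bins_rejected(self):
        truth = VariogramModel("exponential", 0.0, 0.1, 1000.0)
        with pytest.raises(InsufficientDataError):
            fit_model(_synthetic_sv(truth, self.lags[:3]), "exponential")


class TestSelectModel:
    lags = np.arange(250.0, 4700.0, 500.0)

    @pytest.mark.parametrize("family", ["exponential", "spherical", "linear"])
    def test_exact_data_selects_generating_family(self, family):
        truth = VariogramModel(family, nugget=0.01, sill=0.12, range_m=1500.0,
                               slope=3e-5 if family == "linear" else 0.0)
        best = select_model(_synthetic_sv(truth, self.lags))
        assert best.family == family

    def test_selection_is_definitional(self, rng):
        truth = VariogramModel("exponential", 0.005, 0.11, 1300.0)
        sv = _synthetic_sv(truth, self.lags, jitter=0.15, rng=rng)
        fits = [fit_model(sv, fam) for fam in
                ("exponential", "spherical", "gaussian", "linear")]
        best = select_model(sv)
        assert best.rss == pytest.approx(min(f.rss for f in fits), rel=1e-9)


class TestKrige:
    def _field(self, rng, n=25):
        coords = rng.uniform(0, 2000, size=(n, 2))
        values = rng.normal(1.5, 0.4, size=n)
        return coords, values

    def test_exact_interpolation_without_nugget(self, rng):
        coords, values = self._field(rng)
        model = VariogramModel("exponential", nugget=0.0, sill=0.15,
                               range_m=800.0)
        res = krige(coords, values, model, coords[:5])
        np.testing.assert_allclose(res.predictions, values[:5], atol=1e-8)
        np.testing.assert_allclose(res.variances[:5], 0.0, atol=1e-8)

    def test_pure_nugget_reduces_to_neighborhood_mean(self, rng):
        coords, values = self._field(rng)
        model = VariogramModel("exponential", nugget=0.1, sill=0.1,
                               range_m=500.0)
        res = krige(coords, values, model, [[900.0, 900.0]],
                    return_weights=True)
        assert res.predictions[0] == pytest.approx(values.mean(), rel=1e-10)
        np.testing.assert_allclose(res.weights[0], 1 / len(values), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        coords, values = self._field(rng, n=30)
        model = VariogramModel("spherical", nugget=0.02, sill=0.2,
                               range_m=1000.0)
        targets = rng.uniform(-200, 2200, size=(20, 2))
        res = krige(coords, values, model, targets, return_weights=True)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(res.variances >= 0)

    def test_translation_invariance(self, rng):
        coords, values = self._field(rng)
        model = VariogramModel("exponential", nugget=0.01, sill=0.2,
                               range_m=900.0)
        targets = rng.uniform(0, 2000, size=(8, 2))
        base = krige(coords, values, model, targets)
        shifted = krige(coords, values + 10.0, model, targets)
        np.testing.assert_allclose(shifted.predictions,
                                   base.predictions + 10.0, atol=1e-8)
        np.testing.assert_allclose(shifted.variances, base.variances,
                                   atol=1e-10)

    def test_duplicate_points_rejected(self):
        model = VariogramModel("exponential", 0.0, 0.1, 500.0)
        coords = [[0, 0], [0, 0], [100, 100]]
        with pytest.raises(DuplicatePointsError):
            krige(coords, [1.0, 1.0, 2.0], model, [[50, 50]])


class TestLooCrossValidate:
    def test_constant_field_perfect(self, small_grid):
        model = VariogramModel("exponential", 0.01, 0.1, 700.0)
        values = np.full(small_grid.n_nodes, 3.3)
        cv = loo_cross_validate(small_grid.coords(), values, model)
        assert cv.me == pytest.approx(0.0, abs=1e-10)
        assert cv.rmse == pytest.approx(0.0, abs=1e-10)

    def test_rmse_bounds_me(self, survey_grid, plain_field_params):
        table = simulate_layer(survey_grid, plain_field_params, "0-10", 3)
        model = VariogramModel("exponential", 0.0019, 0.127, 1347.0,
                               scale="ln")
        cv = loo_cross_validate(table[["x", "y"]].to_numpy(),
                                np.log(table["soc"].to_numpy()), model)
        assert cv.rmse >= abs(cv.me)
        assert 0.5 < cv.rmsse < 1.6  # loose per-realization band

    def test_too_few_points(self):
        model = VariogramModel("exponential", 0.0, 0.1, 500.0)
        with pytest.raises(InsufficientDataError):
            loo_cross_validate([[0, 0], [1, 1]], [1.0, 2.0], model)


class TestKrigeMap:
    def test_constant_field_gives_constant_map(self, small_grid):
        model = VariogramModel("exponential", 0.0, 0.1, 700.0)
        values = np.full(small_grid.n_nodes, 2.0)
        kmap = krige_map(small_grid.coords(), values, model, 250.0)
        np.testing.assert_allclose(kmap.predictions, 2.0, atol=1e-8)

    def test_node_coinciding_with_sample(self, small_grid, rng):
        model = VariogramModel("exponential", 0.0, 0.1, 700.0)
        values = rng.normal(size=small_grid.n_nodes)
        kmap = krige_map(small_grid.coords(), values, model, 500.0)
        # the map lattice coincides with the sample lattice here
        np.testing.assert_allclose(kmap.predictions.ravel(), values,
                                   atol=1e-7)

    @pytest.mark.parametrize("seed", range(8))
    def test_northward_trend_appears_in_map(self, survey_grid, seed):
        from scipy.stats import spearmanr

        params = FieldParams(mean=1.6, cv=0.368, nugget_ratio=0.02,
                             range_m=1347.0, trend_per_m=-1.5e-4)
        table = simulate_layer(survey_grid, params, "0-10", seed)
        model = VariogramModel("exponential", 0.0025, 0.14, 1347.0,
                               scale="ln")
        kmap = krige_map(table[["x", "y"]].to_numpy(),
                         np.log(table["soc"].to_numpy()), model, 500.0,
                         back_transform="lognormal")
        row_means = kmap.predictions.mean(axis=1)
        rho = spearmanr(kmap.y, row_means).statistic
        assert rho < 0  # SOC decreases northward

    def test_back_transform_modes(self, small_grid, rng):
        model = VariogramModel("exponential", 0.05, 0.15, 700.0, scale="ln")
        values = rng.normal(0.4, 0.3, size=small_grid.n_nodes)
        naive = krige_map(small_grid.coords(), values, model, 250.0,
                          back_transform="naive")
        corrected = krige_map(small_grid.coords(), values, model, 250.0,
                              back_transform="lognormal")
        assert naive.predictions.shape == corrected.predictions.shape
        # the lognormal correction multiplies by exp(var/2 - mu), which
        # varies across the map (larger away from samples)
        log_ratio = np.log(corrected.predictions) - np.log(naive.predictions)
        assert np.ptp(log_ratio) > 1e-3
        with pytest.raises(DomainError):
            krige_map(small_grid.coords(), values, model, 250.0,
                      back_transform="exp10")
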