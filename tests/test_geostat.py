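"""Variograms, WLS fitting, ordinary kriging and LOO model selection."""

import numpy as np
import pytest

from isozone.geodata import PlotExtent
from isozone.geostat import (EmpiricalVariogram, LagSegmentation,
                             VariogramModel, default_cutoff,
                             default_segmentations, empirical_variogram,
                             fit_variogram, krige_points, loo_cross_validate,
                             model_semivariance, ordinary_krige,
                             select_interpolation_model)


class TestCutoff:
    def test_20x50_plot(self, extent_20x50):
        assert default_cutoff(extent_20x50) == pytest.approx(17.95, abs=0.005)

    def test_3_4_5(self):
        assert default_cutoff(PlotExtent(0, 0, 30, 40)) == pytest.approx(50 / 3)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            default_cutoff(PlotExtent(0, 0, 0, 50))


class TestEmpiricalVariogram:
    def test_constant_field_zero_gamma(self, rng):
        x, y = rng.uniform(0, 10, 20), rng.uniform(0, 10, 20)
        z = np.full(20, 3.7)
        ev = empirical_variogram(x, y, z, LagSegmentation((2.0, 4.0, 8.0)), 10)
        assert np.allclose(ev.gammas, 0)

    def test_two_samples_formula(self):
        ev = empirical_variogram(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                                 np.array([0.0, 2.0]),
                                 LagSegmentation((2.0, 4.0)), 5)
        assert ev.gammas.tolist() == [2.0]
        assert ev.counts.tolist() == [1]

    def test_matches_brute_force_pairs(self, rng):
        n = 50
        x, y = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
        z = rng.normal(size=n)
        seg = LagSegmentation.uniform(2.0, 12.0)
        ev = empirical_variogram(x, y, z, seg, 12.0)
        # O(n^2) oracle
        bounds = np.concatenate([[0.0], np.asarray(seg.bounds)])
        sums = np.zeros(len(seg.bounds))
        cnts = np.zeros(len(seg.bounds))
        lsum = np.zeros(len(seg.bounds))
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(x[i] - x[j], y[i] - y[j])
                if d > 12.0 or d <= 0:
                    continue
                b = np.searchsorted(bounds, d, side="left") - 1
                if 0 <= b < len(seg.bounds):
                    sums[b] += (z[i] - z[j]) ** 2
                    cnts[b] += 1
                    lsum[b] += d
        keep = cnts > 0
        np.testing.assert_allclose(ev.counts, cnts[keep])
        np.testing.assert_allclose(ev.gammas, sums[keep] / (2 * cnts[keep]))
        np.testing.assert_allclose(ev.lags, lsum[keep] / cnts[keep])

    def test_all_pairs_beyond_cutoff(self):
        with pytest.raises(ValueError, match="cutoff"):
            empirical_variogram(np.array([0.0, 50.0]), np.array([0.0, 0.0]),
                                np.array([0.0, 1.0]), LagSegmentation((1.0, 2.0)), 2.0)


class TestModelSemivariance:
    def test_spherical_sill_at_range(self):
        m = VariogramModel("spherical", 0, 1, 10)
        assert m(10.0) == pytest.approx(1.0)
        assert m(25.0) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        m = VariogramModel("exponential", 0, 1, 1)
        assert m(1.0) == pytest.approx(1 - np.exp(-1))

    @pytest.mark.parametrize("name", ["nugget", "exponential", "spherical",
                                      "gaussian", "linear", "power"])
    def test_zero_at_origin_and_nondecreasing(self, name):
        m = VariogramModel(name, nugget=0.2, psill=1.0, range_=5.0, exponent=1.5)
        assert m(0.0) == 0.0
        h = np.linspace(0.01, 30, 200)
        g = m(h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_negative_lag_errors(self):
        with pytest.raises(ValueError):
            model_semivariance(VariogramModel("spherical"), -1.0)


class TestFitVariogram:
    def test_noise_free_recovery(self):
        truth = VariogramModel("spherical", 0.1, 0.9, 8.0)
        h = np.linspace(0.5, 15, 12)
        emp = EmpiricalVariogram(h, truth(h), np.full(12, 50), 18.0,
                                 LagSegmentation(tuple(h)))
        fit, obj, conv = fit_variogram(emp, "spherical")
        assert conv
        assert fit.nugget == pytest.approx(0.1, abs=1e-6)
        assert fit.psill == pytest.approx(0.9, abs=1e-6)
        assert fit.range_ == pytest.approx(8.0, abs=1e-5)

    def test_flat_gammas_fit_pure_nugget_shape(self):
        h = np.linspace(1, 10, 8)
        emp = EmpiricalVariogram(h, np.full(8, 0.5), np.full(8, 30), 12.0,
                                 LagSegmentation(tuple(h)))
        fit, _, conv = fit_variogram(emp, "spherical")
        assert conv
        # WLS on constant data: structure contributes ~nothing
        assert fit.nugget + fit.psill * 0.01 == pytest.approx(0.5, abs=0.05)
        assert fit.nugget == pytest.approx(0.5, abs=0.05)

    def test_too_few_bins_errors(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([0.5, 0.6]),
                                 np.array([5, 5]), 5.0, LagSegmentation((1.0, 2.0)))
        with pytest.raises(ValueError, match="bins"):
            fit_variogram(emp, "spherical")


class TestOrdinaryKriging:
    def test_constant_samples_constant_surface(self, small_grid, rng):
        x, y = rng.uniform(0, 10, 12), rng.uniform(0, 10, 12)
        z = np.full(12, 5.0)
        iso = ordinary_krige(x, y, z, VariogramModel("spherical", 0.1, 1, 5),
                             small_grid, cutoff=20)
        np.testing.assert_allclose(iso.prediction.values, 5.0, atol=1e-8)

    def test_pure_nugget_is_sample_mean(self, small_grid):
        # hand-solved 3x3 OK system: equal weights 1/2, mu = -c0/2
        iso = ordinary_krige(np.array([0.5, 9.5]), np.array([0.5, 9.5]),
                             np.array([1.0, 3.0]),
                             VariogramModel("nugget", nugget=1.0),
                             small_grid, cutoff=50)
        vals = iso.prediction.values
        non_sample = np.ones(small_grid.shape, bool)
        non_sample[0, 0] = non_sample[9, 9] = False
        np.testing.assert_allclose(vals[non_sample], 2.0, atol=1e-10)

    def test_zero_nugget_exact_interpolation(self, small_grid, rng):
        # sample locations at cell centres
        x = np.array([0.5, 3.5, 7.5, 2.5, 8.5])
        y = np.array([0.5, 2.5, 8.5, 6.5, 1.5])
        z = rng.normal(size=5)
        iso = ordinary_krige(x, y, z, VariogramModel("spherical", 0.0, 1.0, 6.0),
                             small_grid, cutoff=50)
        for xi, yi, zi in zip(x, y, z):
            i, j = int(yi), int(xi)
            assert iso.prediction.values[i, j] == pytest.approx(zi, abs=1e-8)
            assert iso.variance.values[i, j] == pytest.approx(0.0, abs=1e-8)

    def test_weights_sum_to_one_everywhere(self, small_grid, rng):
        """Unbiasedness: kriging any constant-shifted field shifts predictions
        by exactly that constant, which holds iff weights sum to 1."""
        x, y = rng.uniform(0, 10, 15), rng.uniform(0, 10, 15)
        z = rng.normal(size=15)
        m = VariogramModel("exponential", 0.05, 1.0, 4.0)
        a = ordinary_krige(x, y, z, m, small_grid, cutoff=8).prediction.values
        b = ordinary_krige(x, y, z + 100.0, m, small_grid, cutoff=8).prediction.values
        np.testing.assert_allclose(b - a, 100.0, atol=1e-10)

    def test_variance_positive_away_from_samples(self, small_grid):
        iso = ordinary_krige(np.array([0.5, 9.5]), np.array([0.5, 9.5]),
                             np.array([1.0, 3.0]),
                             VariogramModel("spherical", 0.0, 1.0, 6.0),
                             small_grid, cutoff=50)
        assert iso.variance.values[5, 5] > 0


class TestLOOAndSelection:
    def test_constant_field_rmse_zero_r2_missing(self, rng):
        x, y = rng.uniform(0, 10, 10), rng.uniform(0, 10, 10)
        z = np.full(10, 2.0)
        cv = loo_cross_validate(x, y, z, "nugget", LagSegmentation((3.0, 6.0, 10.0)), 15.0)
        assert cv.converged
        assert cv.rmse == pytest.approx(0.0, abs=1e-9)
        assert cv.r2 is None

    def test_selection_argmin_rmse(self, scattered_samples):
        x, y, z = scattered_samples
        cutoff = 18.0
        segs = [LagSegmentation.uniform(3.0, cutoff)]
        model, seg, cv, report = select_interpolation_model(
            x, y, z, cutoff, model_names=("nugget", "spherical"), segmentations=segs)
        conv = report[report.converged]
        assert cv.rmse == conv.rmse.min()
        assert report.chosen.sum() == 1

    def test_loo_needs_four_samples(self):
        with pytest.raises(ValueError):
            loo_cross_validate(np.arange(3.0), np.zeros(3), np.arange(3.0),
                               "nugget", LagSegmentation((1.0, 2.0)), 5.0)


def test_default_segmentations_catalogue():
    """Six candidate segmentations: five uniform widths and one non-uniform."""
    segs = default_segmentations(17.95)
    assert len(segs) == 6
    names = [s.name for s in segs]
    assert names[:5] == ["uniform_1m", "uniform_1.2m", "uniform_2m",
                         "uniform_3m", "uniform_4m"]
    assert names[5] == "nonuniform"
    assert segs[5].bounds == (1, 2, 3, 4, 5, 6, 7, 9, 12, 15, 18)
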