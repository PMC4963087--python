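"""Constrained-covariance mixture EM, BIC and plateau selection."""

import numpy as np
import pandas as pd
import pytest

from isozone.mixture import (CODES, BICSurface, bic, classify, em_fit,
                             fit_family, n_params, select_model_plateau,
                             ward_init_labels)


def two_blobs(rng, n_per=200, d=3, sep=10.0):
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(sep, 1, (n_per, d))
    X = np.vstack([a, b])
    truth = np.repeat([0, 1], n_per)
    return X, truth


class TestNParams:
    @pytest.mark.parametrize("code,k,d,expected", [
        ("VVV", 3, 3, 29),   # 2 weights + 9 means + 3 SPD matrices of 6
        ("EII", 1, 1, 2),    # one mean + one variance
        ("EEE", 4, 3, 21),   # 3 + 12 + shared d(d+1)/2 = 6
        ("VVI", 2, 3, 1 + 6 + 6),
        ("EEV", 2, 3, 1 + 6 + 3 + 2 * 3),
        ("VEV", 2, 3, 1 + 6 + 2 + 2 + 2 * 3),
    ])
    def test_counting_rule(self, code, k, d, expected):
        assert n_params(code, k, d) == expected

    def test_unknown_code(self):
        with pytest.raises(ValueError):
            n_params("XYZ", 2, 3)


class TestEMFit:
    def test_k1_closed_form_univariate(self):
        """Single Gaussian on {0, 2}: mu = 1, sigma^2 = 1 (MLE), and the
        log-likelihood equals the closed form -(n/2)(log 2pi + log s2 + 1)."""
        fit = em_fit(np.array([[0.0], [2.0]]), 1, "EII")
        assert fit.means[0, 0] == pytest.approx(1.0)
        assert fit.covariances[0, 0, 0] == pytest.approx(1.0)
        assert fit.loglik == pytest.approx(-2 * 0.5 * np.log(2 * np.pi) - 1.0)
        assert fit.loglik == pytest.approx(-2.8379, abs=1e-4)

    @pytest.mark.parametrize("code", CODES)
    def test_k1_mean_is_sample_mean(self, code, rng):
        X = rng.normal(2.0, 1.0, (40, 3))
        fit = em_fit(X, 1, code)
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), atol=1e-8)

    def test_two_blob_recovery(self, rng):
        X, truth = two_blobs(rng)
        fit = em_fit(X, 2, "EII", seed=0)
        means = sorted(fit.means[:, 0])
        assert abs(means[0] - 0.0) < 0.5 and abs(means[1] - 10.0) < 0.5

    @pytest.mark.parametrize("code", CODES)
    def test_loglik_monotone_every_code(self, code, rng):
        """EM never decreases the log-likelihood, for all ten codes."""
        X = np.vstack([rng.normal(0, 1, (60, 3)),
                       rng.normal(3, 2, (60, 3)) @ np.diag([1, 0.5, 2.0])])
        fit = em_fit(X, 3, code, seed=0)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1])).all()

    def test_responsibilities_rows_sum_to_one(self, rng):
        X, _ = two_blobs(rng, n_per=50)
        fit = em_fit(X, 2, "VVV", seed=0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-12)

    def test_n_must_exceed_k(self):
        with pytest.raises(ValueError):
            em_fit(np.zeros((3, 2)), 3, "EII")


class TestConstraintCompliance:
    @pytest.fixture
    def fit_all(self, rng):
        X = np.vstack([rng.normal(0, 1, (80, 3)),
                       rng.normal(4, 1.5, (80, 3))])
        return {code: em_fit(X, 2, code, seed=0) for code in CODES}

    def test_spherical_codes_are_scalar_identity(self, fit_all):
        for code in ("EII", "VII"):
            for S in fit_all[code].covariances:
                off = S - np.diag(np.diagonal(S))
                assert np.abs(off).max() < 1e-10
                assert np.ptp(np.diagonal(S)) < 1e-10

    def test_diagonal_codes_are_diagonal(self, fit_all):
        for code in ("EEI", "VEI", "EVI", "VVI"):
            for S in fit_all[code].covariances:
                off = S - np.diag(np.diagonal(S))
                assert np.abs(off).max() < 1e-10

    def test_equal_volume_codes_share_volume(self, fit_all):
        d = 3
        for code in ("EII", "EEI", "EVI", "EEE", "EEV"):
            vols = [np.linalg.det(S) ** (1 / d) for S in fit_all[code].covariances]
            assert np.ptp(vols) < 1e-8 * max(vols)

    def test_equal_shape_codes_share_shape(self, fit_all):
        for code in ("VEI", "VEV"):
            shapes = []
            for S in fit_all[code].covariances:
                ev = np.sort(np.linalg.eigvalsh(S))[::-1]
                shapes.append(ev / np.prod(ev) ** (1 / 3))
            np.testing.assert_allclose(shapes[0], shapes[1], rtol=1e-6)

    def test_eee_identical_across_components(self, fit_all):
        S = fit_all["EEE"].covariances
        np.testing.assert_allclose(S[0], S[1], atol=1e-12)


class TestVVVOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_given_same_init(self, seed):
        """VVV (fully unconstrained) must agree with an independent
        unconstrained-GMM implementation to 1e-6 in log-likelihood when both
        start from the same hard assignment."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(3, 1.5, (40, 3))])
        n = len(X)
        init = ward_init_labels(X, 2)
        fit = em_fit(X, 2, "VVV", init_labels=init, tol=1e-12, max_iter=5000)
        # sklearn scoring of our converged parameters reproduces our loglik
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky
        gm2 = sklearn.GaussianMixture(n_components=2, covariance_type="full")
        gm2.weights_ = fit.weights
        gm2.means_ = fit.means
        gm2.covariances_ = fit.covariances
        gm2.precisions_cholesky_ = _compute_precision_cholesky(fit.covariances, "full")
        assert gm2.score(X) * n == pytest.approx(fit.loglik, abs=1e-6)
        # sklearn EM from the same hard-label initial parameters reaches the
        # same optimum (both iterate the identical unconstrained EM map)
        w0, m0, c0 = [], [], []
        for j in (0, 1):
            Xi = X[init == j]
            w0.append(len(Xi) / n)
            m0.append(Xi.mean(axis=0))
            c0.append(np.cov(Xi.T, bias=True))
        gm = sklearn.GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=0.0,
            tol=1e-12, max_iter=5000,
            weights_init=np.array(w0), means_init=np.array(m0),
            precisions_init=np.linalg.inv(np.array(c0)))
        gm.fit(X)
        assert gm.score(X) * n == pytest.approx(fit.loglik, abs=1e-6)


class TestBIC:
    def test_hand_value(self):
        fit = em_fit(np.array([[0.0], [2.0]]), 1, "EII")
        assert bic(fit) == pytest.approx(-7.062, abs=1e-3)

    def test_penalty_monotonicity(self, rng):
        X = rng.normal(0, 1, (100, 3))
        f1 = em_fit(X, 1, "EII", seed=0)
        f2 = em_fit(X, 1, "VVV", seed=0)
        # identical k=1 likelihood family: EII nested in VVV, VVV ll >= EII ll
        assert f2.loglik >= f1.loglik - 1e-6
        # but with (almost) equal ll the smaller model wins on BIC
        if abs(f2.loglik - f1.loglik) < 1.0:
            assert bic(f1) > bic(f2) - 2.0


class TestClassify:
    def test_map_and_tie_rule(self, rng):
        X, _ = two_blobs(rng, n_per=30)
        fit = em_fit(X, 2, "EII", seed=0)
        fit.responsibilities[0] = [0.1, 0.9]
        fit.responsibilities[1] = [0.5, 0.5]
        lab = classify(fit)
        assert lab[0] == 1
        assert lab[1] == 0  # exact tie -> lowest component index

    def test_two_blob_ari(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        X, truth = two_blobs(rng)
        fit = em_fit(X, 2, "EII", seed=0)
        ari = sklearn_metrics.adjusted_rand_score(truth, classify(fit))
        assert ari >= 0.95


class TestFamilyAndPlateau:
    def test_single_cloud_selects_k1(self, rng):
        X = rng.normal(0, 1, (150, 3))
        surf = fit_family(X, k_range=range(1, 5), codes=("EII", "VVV"), seed=0)
        code, k = select_model_plateau(surf)
        assert k == 1

    def test_surface_shape_contract(self, rng):
        X, _ = two_blobs(rng, n_per=40)
        surf = fit_family(X, k_range=range(1, 4), codes=("EII", "EEE"), seed=0)
        assert list(surf.values.index) == [1, 2, 3]
        assert list(surf.values.columns) == ["EII", "EEE"]

    def test_plateau_rule_hand_curve(self):
        curve = pd.DataFrame({"EII": [-100.0, -50.0, -20.0, -19.5, -19.4]},
                             index=[1, 2, 3, 4, 5])
        surf = BICSurface(values=curve, fits={}, n=100, d=3)
        code, k = select_model_plateau(surf, tau=0.01)
        assert (code, k) == ("EII", 3)

    def test_steep_curve_falls_back_to_argmax(self, caplog):
        curve = pd.DataFrame({"EII": [-300.0, -200.0, -100.0]}, index=[1, 2, 3])
        surf = BICSurface(values=curve, fits={}, n=100, d=3)
        code, k = select_model_plateau(surf, tau=0.01)
        assert k == 3

    def test_bic_selection_recovers_k(self, rng):
        """Three well-separated components: BIC-based selection finds k = 3
        in at least 90% of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            X = np.vstack([r.normal((0, 0, 0), 1, (70, 3)),
                           r.normal((8, 0, 0), 1, (70, 3)),
                           r.normal((0, 8, 0), 1, (70, 3))])
            surf = fit_family(X, k_range=range(1, 7), codes=("EII", "VII", "EEE"),
                              seed=seed)
            _, k = select_model_plateau(surf)
            hits += (k == 3)
        assert hits >= 18
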