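import math

import numpy as np
import pytest
from scipy import integrate, stats

import sarscore as ss
from sarscore.model import InvertibilityDiagnostic

from conftest import make_params, random_instance


class TestSpatialFilter:
    def test_rho_zero_is_identity(self, lattice9):
        np.testing.assert_array_equal(ss.spatial_filter(0.0, lattice9), np.eye(9))

    def test_direct_arithmetic(self):
        Z = ss.spatial_filter(0.5, np.array([[0.0, 1], [1, 0]]))
        np.testing.assert_allclose(Z, [[1, -0.5], [-0.5, 1]])

    def test_inverse_equals_von_neumann_series(self, rng):
        A = rng.uniform(0.1, 1, size=(3, 3))
        np.fill_diagonal(A, 0)
        W = ss.row_normalize(A)
        rho = 0.7
        Z = ss.spatial_filter(rho, W)
        series = np.zeros((3, 3))
        P = np.eye(3)
        for _ in range(201):
            series += P
            P = P @ (rho * W)
        np.testing.assert_allclose(np.linalg.inv(Z), series, atol=1e-10)

    @pytest.mark.parametrize("rho", [1.0, -1.2])
    def test_invalid_rho_raises(self, rho, lattice9):
        with pytest.raises(ValueError, match="rho"):
            ss.spatial_filter(rho, lattice9)


class TestPredictionError:
    def test_exact_mean_gives_zero(self, rng):
        params, W, X_t, _, mu_t = random_instance(rng, 4)
        Z1 = ss.spatial_filter(params.rho1, W)
        y_t = np.linalg.solve(Z1, X_t @ params.beta + mu_t)
        v = ss.prediction_error(y_t, X_t, params, mu_t, Z1)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_nonspatial_zero_beta_reduces_to_difference(self, rng):
        R = 3
        params = make_params(R, rho1=0.0, beta=(0.0,))
        y = rng.normal(size=R)
        mu = rng.normal(size=R)
        v = ss.prediction_error(y, np.ones((R, 1)), params, mu, np.eye(R))
        np.testing.assert_allclose(v, y - mu)

    def test_matches_explicit_inverse(self, rng):
        params, W, X_t, y_t, mu_t = random_instance(rng, 3)
        Z1 = ss.spatial_filter(params.rho1, W)
        v = ss.prediction_error(y_t, X_t, params, mu_t, Z1)
        Z1inv = np.linalg.inv(Z1)
        expected = y_t - Z1inv @ (X_t @ params.beta) - Z1inv @ mu_t
        np.testing.assert_allclose(v, expected, atol=1e-12)


class TestRobustnessWeights:
    """alpha_t, b_t and u_t: the winsorization mechanics."""

    def test_zero_error_gives_unit_alpha_zero_b_zero_u(self):
        I1 = np.eye(2)
        v = np.zeros(2)
        assert ss.alpha_weight(v, I1, I1, np.zeros(2), 5.0) == 1.0
        assert ss.beta_variate(v, I1, I1, np.zeros(2), 5.0) == 0.0
        np.testing.assert_array_equal(ss.score_innovation(v, I1, I1, 1.0), 0.0)

    def test_scalar_plug_in(self):
        # R=1, Z=1, lam=0, nu=5, v=2: alpha=1.8, b=4/9, u=2/1.8=10/9
        one = np.eye(1)
        v = np.array([2.0])
        alpha = ss.alpha_weight(v, one, one, np.zeros(1), 5.0)
        assert alpha == pytest.approx(1.8, abs=1e-14)
        b = ss.beta_variate(v, one, one, np.zeros(1), 5.0)
        assert b == pytest.approx(4.0 / 9.0, abs=1e-14)
        u = ss.score_innovation(v, one, one, alpha)
        assert u[0] == pytest.approx(10.0 / 9.0, abs=1e-14)
        # both routes of the winsorization identity
        assert u[0] == pytest.approx(2.0 * (1 - b), abs=1e-14)

    def test_alpha_tends_to_one_in_gaussian_limit(self, rng):
        v = rng.normal(size=4)
        alpha = ss.alpha_weight(v, np.eye(4), np.eye(4), np.zeros(4), 1e12)
        assert abs(alpha - 1.0) < 1e-9

    def test_score_is_bounded_as_error_diverges(self):
        one = np.eye(1)
        nu, lam = 5.0, np.zeros(1)
        grid = np.concatenate([np.linspace(0.1, 100, 500), [1e3, 1e4, 1e6]])
        us = []
        for x in grid:
            v = np.array([x])
            a = ss.alpha_weight(v, one, one, lam, nu)
            us.append(abs(ss.score_innovation(v, one, one, a)[0]))
        us = np.array(us)
        # |u| = |v|/(1+v^2/nu) peaks at v=sqrt(nu) then decays to zero
        assert us.max() == pytest.approx(math.sqrt(nu) / 2, rel=1e-3)
        assert us[-1] < 1e-2

    def test_beta_variate_matches_its_law(self, rng):
        # b_t over iid innovation draws follows Beta(R/2, nu/2)
        R, nu = 3, 5.0
        lam = np.full(R, 0.3)
        eta = ss.sample_noise(lam, nu, rng=rng, size=5000)
        q = (eta * (np.exp(-2 * lam)[:, None] * eta)).sum(axis=0) / nu
        b = q / (1 + q)
        # spot-check the vectorized path against the scalar operation
        I3 = np.eye(R)
        for j in range(5):
            assert b[j] == pytest.approx(
                ss.beta_variate(eta[:, j], I3, I3, lam, nu), abs=1e-12
            )
        assert stats.kstest(b, "beta", args=(R / 2, nu / 2)).pvalue > 0.01


class TestSignalUpdate:
    def test_zero_score_decays_signal(self):
        out = ss.signal_update(np.array([1.0, -2.0]), 0.8, np.ones(2), np.zeros(2))
        np.testing.assert_allclose(out, [0.8, -1.6])

    def test_no_memory_case(self):
        out = ss.signal_update(np.array([5.0]), 0.0, np.array([2.0]), np.array([3.0]))
        np.testing.assert_allclose(out, [6.0])

    def test_hand_arithmetic(self):
        out = ss.signal_update(
            np.array([1.0, -1.0]), 0.8, np.array([0.5, 2.0]), np.array([2.0, 1.0])
        )
        np.testing.assert_allclose(out, [1.8, 1.2])


class TestConditionalLogdensity:
    def test_standard_cauchy_mode(self):
        params = make_params(1, nu=1.0, rho1=0.0, rho2=0.0, lam=0.0)
        ld = ss.conditional_logdensity(
            np.zeros(1), np.ones((1, 1)), params, np.zeros(1), np.zeros((1, 1))
        )
        assert ld == pytest.approx(math.log(1 / math.pi), abs=1e-12)

    def test_matches_multivariate_t_oracle(self, rng):
        for _ in range(10):
            params, W, X_t, y_t, mu_t = random_instance(rng, 4)
            ld = ss.conditional_logdensity(y_t, X_t, params, mu_t, W, W)
            Z1 = ss.spatial_filter(params.rho1, W)
            Z2 = ss.spatial_filter(params.rho2, W)
            Z1i, Z2i = np.linalg.inv(Z1), np.linalg.inv(Z2)
            loc = Z1i @ (X_t @ params.beta + mu_t)
            shape = Z1i @ Z2i @ np.diag(np.exp(2 * params.lam)) @ Z2i.T @ Z1i.T
            oracle = stats.multivariate_t(loc, shape, df=params.nu).logpdf(y_t)
            assert ld == pytest.approx(oracle, abs=1e-10)

    def test_density_integrates_to_one(self):
        params = make_params(1, nu=4.0, rho1=0.0, rho2=0.0, lam=0.2, beta=(0.3,))
        X = np.ones((1, 1))
        W = np.zeros((1, 1))

        def dens(y):
            return math.exp(
                ss.conditional_logdensity(np.array([y]), X, params, np.array([0.5]), W)
            )

        total, err = integrate.quad(dens, -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestScoreWrtLocation:
    def test_zero_at_the_mode(self, rng):
        params, W, X_t, _, mu_t = random_instance(rng, 3)
        Z1 = ss.spatial_filter(params.rho1, W)
        y_t = np.linalg.solve(Z1, X_t @ params.beta + mu_t)
        g = ss.score_wrt_location(y_t, X_t, params, mu_t, W, W)
        np.testing.assert_allclose(g, 0.0, atol=1e-10)

    @pytest.mark.parametrize("R", [1, 3, 10])
    def test_matches_finite_differences(self, R, rng):
        params, W, X_t, y_t, mu_t = random_instance(rng, R)
        g = ss.score_wrt_location(y_t, X_t, params, mu_t, W, W)
        num = np.empty(R)
        for r in range(R):
            h = 1e-6 * max(1.0, abs(mu_t[r]))
            e = np.zeros(R)
            e[r] = h
            num[r] = (
                ss.conditional_logdensity(y_t, X_t, params, mu_t + e, W, W)
                - ss.conditional_logdensity(y_t, X_t, params, mu_t - e, W, W)
            ) / (2 * h)
        np.testing.assert_allclose(g, num, rtol=1e-6, atol=1e-8)

    def test_gaussian_limit_of_the_score(self, rng):
        params, W, X_t, y_t, mu_t = random_instance(rng, 3)
        params.nu = 1e10
        g = ss.score_wrt_location(y_t, X_t, params, mu_t, W, W)
        Z1 = ss.spatial_filter(params.rho1, W)
        Z2 = ss.spatial_filter(params.rho2, W)
        v = ss.prediction_error(y_t, X_t, params, mu_t, Z1)
        gauss = Z2.T @ (np.exp(-2 * params.lam) * (Z2 @ Z1 @ v))
        np.testing.assert_allclose(g, gauss, rtol=1e-6)


class TestRunFilter:
    def test_dead_filter_with_zero_loading(self, panel10, lattice10):
        params = make_params(10)
        params.kappa = np.zeros(10)
        out = ss.run_filter(panel10, params, lattice10)
        np.testing.assert_array_equal(out.mu_pred, 0.0)

    def test_loglik_is_sum_of_per_step_densities(self, panel10, params10, lattice10):
        out = ss.run_filter(panel10, params10, lattice10)
        manual = np.array(
            [
                ss.conditional_logdensity(
                    panel10.y[:, t],
                    panel10.X[t],
                    params10,
                    out.mu_pred[:, t],
                    lattice10,
                )
                for t in range(panel10.n_times)
            ]
        )
        np.testing.assert_allclose(out.loglik_t, manual, atol=1e-10)
        assert out.loglik == pytest.approx(manual.sum(), abs=1e-8)

    def test_filter_output_invariants(self, panel10, params10, lattice10):
        out = ss.run_filter(panel10, params10, lattice10)
        assert np.all(out.alpha >= 1.0)
        assert np.all((out.b >= 0) & (out.b < 1))
        # winsorization identity u = Z2 Z1 v (1 - b), pathwise
        Z1 = ss.spatial_filter(params10.rho1, lattice10)
        e = Z1 @ out.v  # Z2 = I here
        np.testing.assert_allclose(out.u, e * (1 - out.b), atol=1e-10)

    def test_initialization_is_forgotten(self, panel10, params10, lattice10):
        a = ss.run_filter(panel10, params10, lattice10, mu_init=np.zeros(10))
        b = ss.run_filter(panel10, params10, lattice10, mu_init=10 * np.ones(10))
        diff = np.linalg.norm(a.mu_pred - b.mu_pred, axis=0)
        assert np.all(diff[200:] < 1e-8)

    def test_martingale_property_of_the_score(self, rng):
        # E[u_t | past] = 0: average over iid innovation draws at fixed signal
        R, nu = 4, 6.0
        params = make_params(R, nu=nu, rho1=0.4, rho2=0.3, lam=0.1)
        A = rng.uniform(0.1, 1, (R, R))
        np.fill_diagonal(A, 0)
        W = ss.row_normalize(A)
        n = 20000
        eta = ss.sample_noise(params.lam, nu, rng=rng, size=n)
        q = (eta * (np.exp(-2 * params.lam)[:, None] * eta)).sum(axis=0) / nu
        u = eta / (1 + q)[None, :]
        mean = u.mean(axis=1)
        mc_se = u.std(axis=1, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(mean) <= 3 * mc_se)


class TestGaussianExpansion:
    def test_zero_point_R2(self):
        assert ss.gaussian_expansion_correction(np.zeros(2), 2, 30.0) == 0.0

    def test_zero_point_R1(self):
        assert ss.gaussian_expansion_correction(np.zeros(1), 1, 30.0) == pytest.approx(
            -1.0 / 120.0
        )

    def test_matches_density_ratio(self, rng):
        R, nu = 3, 1e6
        for _ in range(5):
            y = rng.normal(size=R)
            f = stats.multivariate_t(np.zeros(R), np.eye(R), df=nu).logpdf(y)
            phi = stats.multivariate_normal(np.zeros(R), np.eye(R)).logpdf(y)
            ratio = nu * math.expm1(f - phi)
            corr = nu * ss.gaussian_expansion_correction(y, R, nu)
            assert ratio == pytest.approx(corr, rel=0.01)


class TestInvertibilityDiagnostic:
    def test_linear_case_recovers_phi_decay(self, panel10, lattice10):
        params = make_params(10, phi=0.8)
        params.kappa = np.zeros(10)
        diag = ss.invertibility_diagnostic(
            panel10, params, lattice10, horizon=150, rng=np.random.default_rng(5)
        )
        assert isinstance(diag, InvertibilityDiagnostic)
        assert diag.decay_rate == pytest.approx(math.log(0.8), abs=0.01)
        assert diag.lyapunov_exponent == pytest.approx(math.log(0.8), abs=0.01)
        assert diag.contractive

    def test_contractive_setting_flagged_contractive(self, panel10, params10, lattice10):
        diag = ss.invertibility_diagnostic(
            panel10, params10, lattice10, horizon=300, rng=np.random.default_rng(6)
        )
        assert diag.contractive
        assert diag.lyapunov_exponent < 0
        assert diag.final_spread < 1e-8

    def test_explosive_recursion_flagged(self, panel10, lattice10):
        params = make_params(10, phi=1.05)  # deliberately outside the model class
        params.kappa = np.full(10, 1e-8)
        diag = ss.invertibility_diagnostic(
            panel10, params, lattice10, horizon=150, rng=np.random.default_rng(7)
        )
        assert not diag.contractive
        assert diag.lyapunov_exponent >= 0


def test_gaussian_nesting_of_the_t_density(rng):
    # at nu = 1e8 the Student-t conditional density equals the Gaussian SARAR
    # one at observations of typical Mahalanobis size (the residual expansion
    # term is O(q^2 / nu))
    params, W, X_t, _, mu_t = random_instance(rng, 5)
    params.nu = 1e8
    Z1 = ss.spatial_filter(params.rho1, W)
    Z2 = ss.spatial_filter(params.rho2, W)
    Z1i, Z2i = np.linalg.inv(Z1), np.linalg.inv(Z2)
    loc = Z1i @ (X_t @ params.beta + mu_t)
    S = Z1i @ Z2i @ np.diag(np.exp(2 * params.lam)) @ Z2i.T @ Z1i.T
    for _ in range(5):
        y_t = rng.multivariate_normal(loc, S)
        ld = ss.conditional_logdensity(y_t, X_t, params, mu_t, W, W)
        gauss = stats.multivariate_normal(loc, S).logpdf(y_t)
        assert ld == pytest.approx(gauss, abs=1e-6)
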