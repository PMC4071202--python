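"""Noise models and the assumed-density-filtering core.

The closed-form probit partition functions and the moment-matching updates
are validated against an adaptive-quadrature oracle that integrates the
defining convolution directly — the oracle, not any printed formula, is the
reference.
"""

import numpy as np
import pytest
from scipy.stats import norm

from censorlvm import censor_noise as cn
from censorlvm.censor_noise import (
    NoiseAssignment,
    adf_sweep_dim,
    assimilate,
    censor_likelihood,
    effective_lambda,
    gaussian_log_marginal,
    log_partition,
)

from conftest import gaussian_noise_assignment, quad_log_partition, quad_tilted_moments


class TestCensorLikelihood:
    def test_probit_is_half_at_its_threshold(self):
        assert censor_likelihood(1.5, cn.CENSORED_RIGHT, lam=3.0, b1=1.5) == pytest.approx(0.5)
        assert censor_likelihood(-0.2, cn.CENSORED_LEFT, lam=3.0, b1=-0.2) == pytest.approx(0.5)

    def test_steep_slope_approaches_step_function(self):
        assert censor_likelihood(1.0, cn.CENSORED_RIGHT, lam=1e3, b1=0.0) > 1 - 1e-12
        assert censor_likelihood(-1.0, cn.CENSORED_RIGHT, lam=1e3, b1=0.0) < 1e-12

    def test_interval_midpoint_mass(self):
        # interval of width 2 at slope 1, f at the midpoint: Phi(1) - Phi(-1)
        val = censor_likelihood(0.0, cn.CENSORED_INTERVAL, lam=1.0, b1=-1.0, b2=1.0)
        assert val == pytest.approx(norm.cdf(1) - norm.cdf(-1), abs=1e-12)

    def test_one_sided_likelihoods_are_monotone(self):
        f = np.linspace(-3, 3, 50)
        right = censor_likelihood(f, cn.CENSORED_RIGHT, lam=2.0, b1=0.3)
        left = censor_likelihood(f, cn.CENSORED_LEFT, lam=2.0, b1=0.3)
        assert (np.diff(right) > 0).all()
        assert (np.diff(left) < 0).all()

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            censor_likelihood(0.0, cn.CENSORED_RIGHT, lam=0.0)


class TestLogPartition:
    def test_right_censored_at_bound_is_half(self):
        for v in (0.1, 1.0, 7.0):
            for lam in (0.5, 2.0, 20.0):
                logZ, _, _ = log_partition(1.2, v, cn.CENSORED_RIGHT, lam, b1=1.2)
                assert logZ == pytest.approx(np.log(0.5), abs=1e-12)

    def test_missing_site_is_inert(self):
        assert log_partition(0.3, 2.0, cn.MISSING, lam=1.0) == (0.0, 0.0, 0.0)

    def test_invalid_cavity_variance_rejected(self):
        with pytest.raises(ValueError):
            log_partition(0.0, 0.0, cn.GAUSSIAN, lam=1.0)

    @pytest.mark.parametrize("kind", [cn.CENSORED_RIGHT, cn.CENSORED_LEFT,
                                      cn.CENSORED_INTERVAL, cn.GAUSSIAN])
    def test_closed_forms_match_quadrature_grid(self, kind):
        # the spec'd (mu, v, lam) grid with b = 1
        for mu in (-2.0, 0.0, 3.0):
            for v in (0.1, 1.0, 10.0):
                for lam in (0.5, 2.0, 10.0):
                    kw = dict(b1=1.0, b2=2.5, y=0.7, beta=2.0)
                    got = log_partition(mu, v, kind, lam, **kw)
                    exp = quad_log_partition(mu, v, kind, lam, **kw)
                    assert abs(got[0] - exp[0]) < 1e-8
                    assert abs(got[1] - exp[1]) < 1e-6
                    assert abs(got[2] - exp[2]) < 1e-6

    def test_deep_tail_interval_stays_finite(self):
        logZ, g1, g2 = log_partition(30.0, 0.01, cn.CENSORED_INTERVAL, lam=100.0,
                                     b1=-2.0, b2=0.0)
        assert np.isfinite([logZ, g1, g2]).all()
        assert logZ < -100  # essentially impossible event
        assert g1 < 0  # pulls the mean back toward the interval


class TestSiteUpdates:
    def test_gaussian_site_recovers_conjugate_update(self, rng):
        # ADF with Gaussian likelihoods is the exact sequential GP update
        X = rng.standard_normal((6, 2))
        K = X @ X.T + 0.5 * np.eye(6)
        y = rng.standard_normal((6, 1))
        noise = gaussian_noise_assignment(y, beta=3.0)
        mu, Sigma, m, tau, lz, _ = adf_sweep_dim(K, noise, 0)
        from censorlvm.kernels import add_jitter
        Kj = add_jitter(K)
        A = Kj + np.eye(6) / 3.0
        np.testing.assert_allclose(mu, Kj @ np.linalg.solve(A, y[:, 0]), atol=1e-10)
        np.testing.assert_allclose(tau, 3.0)
        np.testing.assert_allclose(m, y[:, 0])

    def test_missing_entries_leave_state_untouched(self, rng):
        # constant-diagonal kernel so full and subset sweeps apply the same
        # relative jitter and the equivalence is exact
        X = rng.standard_normal((5, 2))
        d2 = np.sum((X[:, None] - X[None]) ** 2, axis=-1)
        K = 1.3 * np.exp(-0.5 * d2)
        y = rng.standard_normal((5, 1))
        kind = np.zeros((5, 1), int)
        kind[2, 0] = cn.MISSING
        noise = NoiseAssignment(kind=kind, y=y, b1=np.zeros((5, 1)), b2=np.ones((5, 1)),
                                beta=2.0)
        mu, Sigma, m, tau, lz, _ = adf_sweep_dim(K, noise, 0)
        assert tau[2] == 0.0 and lz[2] == 0.0
        # equivalent to deleting the point from this dimension's GP
        keep = np.array([0, 1, 3, 4])
        noise_sub = gaussian_noise_assignment(y[keep], beta=2.0)
        _, _, _, _, lz_sub, _ = adf_sweep_dim(K[np.ix_(keep, keep)], noise_sub, 0)
        assert lz.sum() == pytest.approx(lz_sub.sum(), abs=1e-9)

    def test_matched_moments_agree_with_quadrature(self):
        # single right-censored observation against a N(0, 1) prior
        prior_v, b, lam = 1.0, 0.0, 2.0
        K = np.array([[prior_v]])
        kind = np.array([[cn.CENSORED_RIGHT]])
        noise = NoiseAssignment(kind=kind, y=np.zeros((1, 1)),
                                b1=np.full((1, 1), b), b2=np.full((1, 1), b + 1),
                                lam=lam)
        mu, Sigma, *_ = adf_sweep_dim(K, noise, 0)
        jitter_v = prior_v * (1 + 1e-6)
        mean_q, var_q = quad_tilted_moments(0.0, jitter_v, cn.CENSORED_RIGHT, lam, b1=b)
        assert mu[0] == pytest.approx(mean_q, abs=1e-6)
        assert Sigma[0, 0] == pytest.approx(var_q, abs=1e-6)

    @pytest.mark.parametrize("kind,sign", [(cn.CENSORED_RIGHT, 1.0),
                                           (cn.CENSORED_LEFT, -1.0)])
    def test_posterior_mean_moves_toward_censored_side(self, kind, sign):
        for mu0 in (-1.0, 0.0, 2.0):
            K = np.array([[1.5]])
            noise = NoiseAssignment(kind=np.array([[kind]]), y=np.zeros((1, 1)),
                                    b1=np.full((1, 1), 0.4), b2=np.full((1, 1), 1.4),
                                    lam=3.0)
            # shift the prior by mu0 via the bound instead (prior mean is 0)
            noise.b1 -= mu0
            mu, *_ = adf_sweep_dim(K, noise, 0)
            assert sign * mu[0] > 0.0

    def test_moment_matching_on_random_grid(self, rng):
        # randomized property check of the matched mean/variance, >= 200 draws
        n_checked = 0
        while n_checked < 200:
            v = float(rng.uniform(0.05, 5.0))
            mu0 = float(rng.uniform(-3, 3))
            lam = float(rng.uniform(0.3, 8.0))
            b = float(rng.uniform(-2, 2))
            kind = int(rng.choice([cn.CENSORED_RIGHT, cn.CENSORED_LEFT,
                                   cn.CENSORED_INTERVAL]))
            b2 = b + float(rng.uniform(0.5, 3.0))
            logZ, g1, g2 = log_partition(mu0, v, kind, lam, b1=b, b2=b2)
            mean_m = mu0 + v * g1
            var_m = v + v * v * g2
            mean_q, var_q = quad_tilted_moments(mu0, v, kind, lam, b1=b, b2=b2)
            assert mean_m == pytest.approx(mean_q, abs=1e-6)
            assert var_m == pytest.approx(var_q, abs=1e-6)
            n_checked += 1


class TestAssimilate:
    def test_exact_for_all_gaussian_data(self, rng):
        X = rng.standard_normal((8, 2))
        K = X @ X.T + 0.3 * np.eye(8)
        y = rng.standard_normal((8, 3))
        noise = gaussian_noise_assignment(y, beta=2.0)
        state = assimilate(noise, K)
        exact = sum(gaussian_log_marginal(K, y[:, d], 2.0) for d in range(3))
        assert state.log_marginal == pytest.approx(exact, abs=1e-8)

    def test_fully_missing_dimension_contributes_nothing(self, rng):
        X = rng.standard_normal((6, 2))
        K = X @ X.T + 0.3 * np.eye(6)
        y = rng.standard_normal((6, 2))
        kind = np.zeros((6, 2), int)
        kind[:, 1] = cn.MISSING
        noise = NoiseAssignment(kind=kind, y=y, b1=np.zeros((6, 2)), b2=np.ones((6, 2)),
                                beta=2.0)
        state = assimilate(noise, K)
        assert state.log_marginal_dim(1) == 0.0
        assert (state.site_tau[:, 1] == 0.0).all()

    def test_log_marginal_factorizes_over_dimensions(self, rng):
        X = rng.standard_normal((6, 2))
        K = X @ X.T + 0.3 * np.eye(6)
        kind = np.zeros((6, 3), int)
        kind[1, 0] = cn.CENSORED_RIGHT
        kind[4, 2] = cn.CENSORED_LEFT
        y = rng.standard_normal((6, 3))
        noise = NoiseAssignment(kind=kind, y=y, b1=np.full((6, 3), 0.5),
                                b2=np.full((6, 3), 1.5), beta=2.0, lam=4.0)
        state = assimilate(noise, K)
        total = sum(state.log_marginal_dim(d) for d in range(3))
        assert state.log_marginal == pytest.approx(total, rel=1e-12)
        # each dimension alone reproduces its block
        for d in range(3):
            solo = NoiseAssignment(kind=kind[:, [d]], y=y[:, [d]],
                                   b1=np.full((6, 1), 0.5), b2=np.full((6, 1), 1.5),
                                   beta=2.0, lam=4.0)
            assert assimilate(solo, K).log_marginal == pytest.approx(
                state.log_marginal_dim(d), rel=1e-12)

    def test_covariance_blocks_stay_symmetric_psd(self, rng):
        X = rng.standard_normal((7, 2))
        K = X @ X.T + 0.3 * np.eye(7)
        kind = np.zeros((7, 2), int)
        kind[0, 0] = cn.CENSORED_RIGHT
        kind[3, 1] = cn.CENSORED_INTERVAL
        noise = NoiseAssignment(kind=kind, y=rng.standard_normal((7, 2)),
                                b1=np.full((7, 2), -0.5), b2=np.full((7, 2), 1.0),
                                beta=2.0, lam=5.0)
        state = assimilate(noise, K)
        for d in range(2):
            S = state.Sigma[d]
            np.testing.assert_allclose(S, S.T, atol=1e-10)
            assert np.linalg.eigvalsh(S).min() > -1e-9 * np.trace(S)


class TestLambdaEquivalence:
    def test_steep_slope_plus_diagonal_variance_matches_shallow_slope(self, rng):
        # the white-noise kernel trick: lam0 with extra censored-diagonal
        # variance v equals slope 1/sqrt(1/lam0^2 + v) with none
        X = rng.standard_normal((7, 2))
        K = X @ X.T + 0.4 * np.eye(7)
        kind = np.zeros((7, 2), int)
        kind[1, 0] = kind[4, 0] = cn.CENSORED_RIGHT
        kind[3, 1] = cn.CENSORED_LEFT
        y = rng.standard_normal((7, 2))
        lam, lam0 = 3.0, 100.0
        v_add = 1.0 / lam**2 - 1.0 / lam0**2
        shallow = NoiseAssignment(kind=kind, y=y, b1=np.full((7, 2), 0.3),
                                  b2=np.full((7, 2), 1.3), beta=2.0, lam=lam)
        steep = NoiseAssignment(kind=kind, y=y, b1=np.full((7, 2), 0.3),
                                b2=np.full((7, 2), 1.3), beta=2.0, lam=lam0)
        Ks = np.repeat(K[None], 2, axis=0)
        Ks_steep = Ks.copy()
        for d in range(2):
            Ks_steep[d][np.diag_indices(7)] += v_add * shallow.censor_masks()[d]
        a = assimilate(shallow, Ks)
        b = assimilate(steep, Ks_steep)
        assert a.log_marginal == pytest.approx(b.log_marginal, abs=1e-6)
        assert effective_lambda(lam0, v_add) == pytest.approx(lam, rel=1e-12)
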