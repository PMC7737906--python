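"""Core test forms: L/Q/M statistics, mixture chi-squared, ACAT, HMP, Landau.

Oracles: closed-form chi-squared limits, dense-trapezoid characteristic-
function inversion (independent of the adaptive-quadrature implementation),
Monte-Carlo tails, and scipy's MVN cdf for the rectangle algorithm.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, multivariate_normal, norm

from omnigene.core_tests import (
    acat_combine,
    hmp_combine,
    hmp_location,
    landau_cdf,
    ltype_test,
    mixture_chisq_sf,
    mixture_chisq_sf_batch,
    mtype_test,
    mvn_rectangle_prob,
    qtype_eigenvalues,
    qtype_test,
)
from tests.conftest import ar1, exchangeable


def imhof_trapezoid_oracle(q, lam, u_max=4000.0, n=4_000_000):
    """Independent CF inversion: plain dense trapezoid of the Imhof integrand."""
    lam = np.asarray(lam, float)
    u = np.linspace(1e-9, u_max, n)
    theta = 0.5 * np.sum(np.arctan(np.outer(lam, u)), axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.sum(np.log1p(np.outer(lam, u) ** 2), axis=0)
    integrand = np.sin(theta) / (u * np.exp(np.minimum(log_rho, 700)))
    return 0.5 + np.trapezoid(integrand, u) / np.pi


class TestLType:
    def test_single_variant_is_z_test(self):
        out = ltype_test([2.0], [1.0], [[1.0]])
        assert out.stat == pytest.approx(2.0)
        assert out.p == pytest.approx(2 * norm.sf(2.0), abs=1e-12)

    def test_independent_pair(self):
        out = ltype_test([1.0, 1.0], [1.0, 1.0], np.eye(2))
        assert out.stat == pytest.approx(math.sqrt(2))
        assert out.p == pytest.approx(2 * norm.sf(math.sqrt(2)), abs=1e-12)

    def test_perfect_ld_denominator(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = ltype_test([1.0, 1.0], [1.0, 1.0], R)
        assert out.stat == pytest.approx(1.0)

    def test_degenerate_weights_error(self):
        R = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            ltype_test([1.0, 1.0], [1.0, 1.0], R)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=4)
        w = rng.normal(size=4)
        R = ar1(4, 0.5)
        assert ltype_test(z, w, R).p == pytest.approx(ltype_test(z, -w, R).p)


class TestQType:
    def test_single_variant_chi2(self):
        out = qtype_test([2.0], [1.0], [[1.0]])
        assert out.stat == pytest.approx(4.0)
        assert out.p == pytest.approx(chi2.sf(4.0, 1), abs=1e-10)

    def test_identity_ld_chi2_m(self):
        out = qtype_test([1.0, 1.0, 1.0], np.ones(3), np.eye(3))
        assert out.stat == pytest.approx(3.0)
        assert out.p == pytest.approx(chi2.sf(3.0, 3), abs=1e-8)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            qtype_test([1.0, 1.0], [1.0, -1.0], np.eye(2))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            qtype_test([1.0, 1.0], [0.0, 0.0], np.eye(2))

    def test_eigenvalue_trace_identity(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 2.0, size=6)
        R = ar1(6, 0.6)
        lam = qtype_eigenvalues(w, R)
        assert lam.sum() == pytest.approx(w.sum(), abs=1e-8)

    def test_monte_carlo_oracle_ar1(self):
        """Five-variant instance vs a million-draw MVN quadratic-form tail."""
        rng = np.random.default_rng(7)
        m = 5
        R = ar1(m, 0.6)
        w = rng.uniform(0.2, 1.5, size=m)
        z = rng.normal(size=m) * 1.5
        out = qtype_test(z, w, R)
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((10**6, m)) @ L.T
        tail = ((X**2) @ w >= out.stat).mean()
        se = math.sqrt(max(tail * (1 - tail), 1e-12) / 10**6)
        assert abs(out.p - tail) <= 3 * se


class TestMixtureChisqSF:
    def test_chi2_1_quantile(self):
        assert mixture_chisq_sf(3.841458820694124, [1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_chi2_2_closed_form(self):
        assert mixture_chisq_sf(2.0, [1.0, 1.0]) == pytest.approx(math.exp(-1), abs=1e-9)

    def test_matches_independent_cf_quadrature(self):
        lam = [2.0, 1.0, 0.5]
        for q in [1.0, 3.5, 7.0, 12.0]:
            want = imhof_trapezoid_oracle(q, lam)
            assert mixture_chisq_sf(q, lam) == pytest.approx(want, abs=5e-6)

    def test_nonincreasing_and_one_at_zero(self):
        lam = [1.5, 0.7, 0.3]
        qs = np.linspace(0, 30, 200)
        ps = np.array([mixture_chisq_sf(q, lam) for q in qs])
        assert ps[0] == 1.0
        assert np.all(np.diff(ps) <= 1e-12)

    def test_deep_tail_saddlepoint_continuity(self):
        lam = [2.0, 1.0, 0.5]
        p_hi, info_hi = mixture_chisq_sf(100.0, lam, return_info=True)
        p_lo, info_lo = mixture_chisq_sf(120.0, lam, return_info=True)
        assert info_hi["method"] == "imhof"
        assert info_lo["method"] == "saddlepoint"
        assert 0 < p_lo < p_hi < 1e-9

    def test_nonfinite_statistic_error(self):
        with pytest.raises(ValueError):
            mixture_chisq_sf(float("nan"), [1.0])

    def test_batch_matches_pointwise(self):
        rng = np.random.default_rng(5)
        lam = np.abs(rng.normal(size=12))
        qs = rng.uniform(0.0, 5 * lam.sum(), size=300)
        batch = mixture_chisq_sf_batch(qs, lam)
        direct = np.array([mixture_chisq_sf(q, lam) for q in qs[::25]])
        np.testing.assert_allclose(batch[::25], direct, rtol=2e-3)


class TestMType:
    def test_single_variant(self):
        out = mtype_test([1.7], [[1.0]])
        assert out.p == pytest.approx(2 * norm.sf(1.7), abs=1e-12)

    def test_identity_ld_sidak(self):
        z = np.array([1.2, -0.5, 2.1, 0.3, 1.9])
        out = mtype_test(z, np.eye(5))
        p_min = 2 * norm.sf(2.1)
        assert out.p == pytest.approx(1 - (1 - p_min) ** 5, abs=1e-6)

    def test_exchangeable_monte_carlo_oracle(self):
        rng = np.random.default_rng(11)
        R = exchangeable(4, 0.5)
        z = np.array([1.8, -0.7, 2.4, 0.9])
        out = mtype_test(z, R)
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((10**6, 4)) @ L.T
        t = np.abs(z).max()
        tail = (np.max(np.abs(X), axis=1) >= t).mean()
        se = math.sqrt(tail * (1 - tail) / 10**6)
        assert abs(out.p - tail) <= 3 * se

    def test_rectangle_against_scipy_mvn(self):
        R = ar1(6, 0.6)
        t = 2.2
        got, err = mvn_rectangle_prob(np.full(6, -t), np.full(6, t), R)
        want = multivariate_normal.cdf(
            np.full(6, t), mean=np.zeros(6), cov=R,
            lower_limit=np.full(6, -t), rng=np.random.default_rng(0),
        )
        assert got == pytest.approx(want, abs=max(5 * err, 1e-4))

    def test_reproducible(self):
        R = ar1(5, 0.4)
        z = np.array([0.5, 1.0, -2.0, 0.3, 1.4])
        assert mtype_test(z, R).p == mtype_test(z, R).p

    def test_at_least_min_p(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(2, 8)
            R = ar1(int(m), rng.uniform(0, 0.9))
            z = rng.normal(size=int(m)) * 1.5
            p_min = float(2 * norm.sf(np.abs(z).max()))
            assert mtype_test(z, R).p >= p_min - 1e-12


class TestACAT:
    def test_single_input_identity(self):
        for p in [1e-8, 0.3, 0.97]:
            assert acat_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_cauchy_median(self):
        assert acat_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_value_tangent_formula(self):
        # direct evaluation of the tangent formula at full precision
        T = 0.5 * (math.tan((0.5 - 0.01) * math.pi) + math.tan((0.5 - 0.5) * math.pi))
        want = 0.5 - math.atan(T) / math.pi
        got = acat_combine([0.01, 0.5])
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(0.0200, abs=2e-4)

    def test_tiny_p_tail_approximation(self):
        got = acat_combine([1e-20, 0.5])
        assert got == pytest.approx(2e-20, rel=1e-3)

    def test_p_of_one_handled(self):
        assert 0 < acat_combine([1.0, 1.0]) <= 1.0

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], []])
    def test_invalid_inputs_error(self, bad):
        with pytest.raises(ValueError):
            acat_combine(bad)

    def test_weights_normalized(self):
        p = [0.01, 0.2, 0.9]
        assert acat_combine(p, [1, 1, 1]) == pytest.approx(acat_combine(p, [7, 7, 7]))


class TestHMP:
    def test_single_input_short_circuit(self):
        for p in [1e-6, 0.42, 1.0]:
            assert hmp_combine([p]) == p

    def test_location_increasing_in_m(self):
        mus = [hmp_location(m) for m in range(1, 200)]
        assert all(b > a for a, b in zip(mus, mus[1:]))

    def test_matches_landau_tail_quadrature(self):
        """Twenty p-values vs quadrature of the printed density over the tail.

        The printed-density parameterization reaches the standard-Landau
        loc-scale form via loc = mu + (2 sigma/pi) log(sigma); the combiner's
        location corresponds to mu = log m + 1 - gamma in the printed form.
        """
        from scipy.integrate import quad

        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, size=20)
        got = hmp_combine(p)
        x = float(np.mean(1.0 / p))
        sigma = math.pi / 2
        mu_printed = hmp_location(20) - math.log(sigma)

        def density(y):
            g = lambda u: math.exp(-u) * math.cos(
                (y - mu_printed) * u / sigma + (2 * u / math.pi) * math.log(u / sigma)
            )
            return quad(g, 0, np.inf, limit=400)[0] / (math.pi * sigma)

        cdf_at_x, _ = quad(density, mu_printed - 60 * sigma, x, limit=800)
        assert got == pytest.approx(1.0 - cdf_at_x, abs=1e-7)

    def test_greater_equal_min_p(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(2, 30))
            assert hmp_combine(p) >= p.min() - 1e-15

    def test_null_tail_rates_iid(self):
        """Tail calibration at m=50: empirical rejection close to nominal."""
        rng = np.random.default_rng(12)
        P = rng.uniform(size=(40_000, 50))
        out = np.array([0.0])
        from omnigene.core_tests import hmp_combine_rows

        out = hmp_combine_rows(P)
        for alpha, tol in [(0.05, 0.004), (0.005, 0.0015)]:
            assert abs((out <= alpha).mean() - alpha) < tol


class TestLandau:
    def test_left_tail_negligible(self):
        mu, s = 3.0, math.pi / 2
        assert landau_cdf(mu - 50 * s, mu, s) < 1e-6

    def test_monotone_on_grid(self):
        x = np.linspace(-20, 200, 1000)
        vals = landau_cdf(x, 2.0, math.pi / 2)
        assert np.all(np.diff(vals) >= -1e-14)
        assert vals[0] < 1e-4 and vals[-1] > 0.95

    def test_matches_printed_density_quadrature(self):
        from scipy.integrate import quad

        mu, s = 3.0, math.pi / 2

        def density(y):
            g = lambda u: math.exp(-u) * math.cos(
                (y - mu) * u / s + (2 * u / math.pi) * math.log(u / s)
            )
            return quad(g, 0, np.inf, limit=400)[0] / (math.pi * s)

        for x in [mu - 2 * s, mu, mu + 2 * s, mu + 10 * s]:
            want, _ = quad(density, mu - 60 * s, x, limit=800)
            assert landau_cdf(x, mu, s) == pytest.approx(want, abs=1e-8)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            landau_cdf(0.0, 0.0, -1.0)


class TestSharedInvariants:
    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        z = rng.normal(size=m) * 1.5
        w = rng.uniform(0.1, 2.0, size=m)
        R = ar1(m, float(rng.uniform(0, 0.8)))
        perm = rng.permutation(m)
        Rp = R[np.ix_(perm, perm)]
        assert ltype_test(z, w, R).p == pytest.approx(
            ltype_test(z[perm], w[perm], Rp).p, rel=1e-9)
        assert qtype_test(z, w, R).p == pytest.approx(
            qtype_test(z[perm], w[perm], Rp).p, rel=1e-6)
        p1 = 2 * norm.sf(np.abs(z))
        assert acat_combine(p1, w) == pytest.approx(
            acat_combine(p1[perm], w[perm]), rel=1e-12)
        assert hmp_combine(p1, w) == pytest.approx(
            hmp_combine(p1[perm], w[perm]), rel=1e-12)

    def test_all_forms_return_valid_p(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            m = int(rng.integers(1, 9))
            z = rng.normal(size=m) * rng.uniform(0.5, 3)
            w = rng.uniform(0.01, 2.0, size=m)
            R = ar1(m, float(rng.uniform(0, 0.9)))
            p1 = 2 * norm.sf(np.abs(z))
            for p in (
                ltype_test(z, w, R).p,
                qtype_test(z, w, R).p,
                mtype_test(z, R).p,
                acat_combine(p1, w),
                hmp_combine(p1, w),
            ):
                assert 0 < p <= 1.0
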