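import numpy as np
import pytest
from scipy import integrate, stats

from gwnr import (
    DegenerateTestError,
    InvalidInputError,
    f_quantile,
    fit_gwnr,
    fit_mnr,
    gamma_traces,
    gof_test,
    satterthwaite,
    sse_chi2_approx_check,
    tau_traces,
)


def _random_projection(n, k, rng):
    X = rng.standard_normal((n, k))
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


class TestGammaTraces:
    def test_zero_smoother_gives_identity_traces(self):
        g1, g2 = gamma_traces(np.zeros((7, 7)))
        assert (g1, g2) == (7.0, 7.0)

    def test_identity_smoother_gives_zero(self):
        g1, g2 = gamma_traces(np.eye(5))
        assert (g1, g2) == (0.0, 0.0)

    @pytest.mark.parametrize("n", [6, 12, 20])
    def test_eigenvalue_sum_oracle(self, n, rng):
        # gamma_i must equal sums of powers of the eigenvalues of (I-G)'(I-G)
        G = rng.standard_normal((n, n)) * 0.3
        g1, g2 = gamma_traces(G)
        A = (np.eye(n) - G).T @ (np.eye(n) - G)
        lam = np.linalg.eigvalsh(A)
        assert g1 == pytest.approx(lam.sum(), abs=1e-8)
        assert g2 == pytest.approx((lam**2).sum(), abs=1e-8)

    def test_rejects_non_square(self):
        with pytest.raises(InvalidInputError):
            gamma_traces(np.zeros((3, 4)))


class TestTauTraces:
    def test_projection_equal_to_smoother_is_degenerate(self, rng):
        L = _random_projection(8, 3, rng)
        with pytest.raises(DegenerateTestError):
            tau_traces(L, L)
        t1, t2 = tau_traces(L, L, allow_degenerate=True)
        assert t1 == pytest.approx(0.0, abs=1e-10)
        assert t2 == pytest.approx(0.0, abs=1e-10)

    def test_saturated_global_model_negates_gamma(self, rng):
        G = rng.standard_normal((6, 6)) * 0.2
        g1, _ = gamma_traces(G)
        t1, _ = tau_traces(np.eye(6), G, allow_degenerate=True)
        assert t1 == pytest.approx(-g1, abs=1e-10)

    @pytest.mark.parametrize("n", [6, 12, 20])
    def test_eigenvalue_sum_oracle(self, n, rng):
        L = _random_projection(n, 3, rng)
        G = rng.standard_normal((n, n)) * 0.2
        t1, t2 = tau_traces(L, G, allow_degenerate=True)
        B = (np.eye(n) - L) - (np.eye(n) - G).T @ (np.eye(n) - G)
        lam = np.linalg.eigvalsh((B + B.T) / 2)
        assert t1 == pytest.approx(lam.sum(), abs=1e-8)
        assert t2 == pytest.approx((lam**2).sum(), abs=1e-8)

    def test_non_projection_l_rejected(self, rng):
        M = rng.standard_normal((5, 5))
        symmetric_not_idempotent = (M + M.T) / 2
        with pytest.raises(InvalidInputError, match="idempotent"):
            tau_traces(symmetric_not_idempotent, np.zeros((5, 5)))
        with pytest.raises(InvalidInputError, match="symmetric"):
            tau_traces(M, np.zeros((5, 5)))


class TestSatterthwaite:
    def test_projection_limit_is_exact_chi_square(self):
        assert satterthwaite(4.0, 4.0) == (1.0, 4.0)

    def test_arithmetic(self):
        c, r = satterthwaite(4.0, 2.0)
        assert (c, r) == (0.5, 8.0)

    def test_moment_matching_identities(self, rng):
        # c*r and 2*c^2*r must reproduce tr(A) and 2*tr(A^2) exactly
        G = rng.standard_normal((9, 9)) * 0.3
        g1, g2 = gamma_traces(G)
        c, r = satterthwaite(g1, g2)
        assert c * r == pytest.approx(g1, rel=1e-10)
        assert 2 * c**2 * r == pytest.approx(2 * g2, rel=1e-10)

    def test_rejects_non_positive(self):
        with pytest.raises(InvalidInputError):
            satterthwaite(0.0, 1.0)


class TestChiSquareApproximation:
    def test_projection_case_is_exact(self, rng):
        # G a projection of rank k: SSE/sigma^2 is exactly chi2_{n-k}
        G = _random_projection(12, 4, rng)
        ks = sse_chi2_approx_check(G, reps=5000, seed=1)
        assert ks < 0.03

    def test_heterogeneous_eigenvalues_stay_close(self, small_fits):
        _, _, gwnr = small_fits
        ks = sse_chi2_approx_check(gwnr.G, reps=5000, seed=2)
        assert ks < 0.05

    def test_requires_enough_reps(self, rng):
        with pytest.raises(InvalidInputError):
            sse_chi2_approx_check(np.zeros((4, 4)), reps=10)


class TestFQuantile:
    def test_published_critical_values(self):
        # critical values quoted for the two case studies
        assert f_quantile(0.05, 53.85, 37.49) == pytest.approx(1.67, abs=0.01)
        assert f_quantile(0.05, 27.88, 11.15) == pytest.approx(2.56, abs=0.01)

    def test_median_has_half_mass_by_quadrature(self):
        # independent check: integrate the F density up to the quantile
        d1, d2 = 7.3, 11.9
        q = f_quantile(0.5, d1, d2)
        mass, _ = integrate.quad(lambda x: stats.f.pdf(x, d1, d2), 0, q)
        assert mass == pytest.approx(0.5, abs=1e-8)

    def test_alpha_validation(self):
        with pytest.raises(InvalidInputError):
            f_quantile(1.5, 3, 3)


class TestGofTest:
    def test_uniform_weights_are_degenerate(self, small_data, uniform_spec):
        data, _ = small_data
        gwnr = fit_gwnr(data, uniform_spec)
        mnr = fit_mnr(data.y, gwnr.design)
        with pytest.raises(DegenerateTestError):
            gof_test(data.y, mnr, gwnr)

    def test_quadratic_form_equals_sse_difference_form(self, small_fits):
        data, mnr, gwnr = small_fits
        res = gof_test(data.y, mnr, gwnr)
        f_from_sse = ((mnr.sse - gwnr.sse) / res.traces.tau1) / (gwnr.sse / res.traces.gamma1)
        assert res.f_stat == pytest.approx(f_from_sse, rel=1e-10)

    def test_report_internal_consistency(self, small_fits):
        data, mnr, gwnr = small_fits
        res = gof_test(data.y, mnr, gwnr, alpha=0.05)
        assert res.df1 == pytest.approx(res.traces.tau1**2 / res.traces.tau2)
        assert res.df2 == pytest.approx(res.traces.gamma1**2 / res.traces.gamma2)
        assert res.reject_h0 == (res.f_stat > res.critical) == (res.p_value < res.alpha)
        assert 0 <= res.p_value <= 1
        assert res.traces.gamma2 <= res.traces.gamma1**2 + 1e-12

    def test_alpha_changes_decision_not_statistic(self, small_fits):
        data, mnr, gwnr = small_fits
        r1 = gof_test(data.y, mnr, gwnr, alpha=0.05)
        r2 = gof_test(data.y, mnr, gwnr, alpha=0.5)
        assert r1.f_stat == r2.f_stat and r1.p_value == r2.p_value
        assert r1.critical > r2.critical
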