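import numpy as np
import pytest
from dataclasses import replace

from gwnr import (
    DesignMatrix,
    InvalidInputError,
    SingularDesignError,
    SimulationScenario,
    fit_gwnr,
    fit_local,
    fit_mnr,
    gen_dataset,
)
from gwnr.fitting import expected_rank
from gwnr.weights import kernel_weights, pairwise_distance


def _full_rank_design(n, m, rng):
    """A plain random design without the structural intercept/half aliasing."""
    values = np.column_stack([np.ones(n), rng.standard_normal((n, m - 1))])
    labels = ("intercept",) + tuple(f"c{j}" for j in range(1, m))
    return DesignMatrix(values, labels)


class TestFitMnr:
    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: solve (Q'Q) eta = Q'y directly
        design = _full_rank_design(12, 4, rng)
        y = rng.standard_normal(12)
        fit = fit_mnr(y, design)
        Q = design.values
        eta_oracle = np.linalg.solve(Q.T @ Q, Q.T @ y)
        np.testing.assert_allclose(fit.eta, eta_oracle, atol=1e-8)
        np.testing.assert_allclose(fit.L, Q @ np.linalg.solve(Q.T @ Q, Q.T), atol=1e-8)

    def test_response_in_span_gives_zero_sse(self, rng):
        design = _full_rank_design(15, 3, rng)
        y = design.values @ np.array([1.0, -2.0, 0.5])
        assert fit_mnr(y, design).sse == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_response_fits_zero(self, rng):
        design = _full_rank_design(10, 3, rng)
        # project a random vector onto the orthocomplement of the columns
        Q, _ = np.linalg.qr(design.values)
        y = rng.standard_normal(10)
        y = y - Q @ (Q.T @ y)
        fit = fit_mnr(y, design)
        np.testing.assert_allclose(fit.fitted, 0.0, atol=1e-10)

    def test_hat_matrix_is_projection_with_trace_rank(self, small_fits):
        _, mnr, _ = small_fits
        L = mnr.L
        np.testing.assert_allclose(L, L.T, atol=1e-10)
        np.testing.assert_allclose(L @ L, L, atol=1e-10)
        assert np.trace(L) == pytest.approx(expected_rank(mnr.design), abs=1e-8)

    def test_duplicated_column_is_an_error(self, rng):
        v = rng.standard_normal(10)
        values = np.column_stack([np.ones(10), v, v])
        design = DesignMatrix(values, ("intercept", "a", "a_copy"))
        with pytest.raises(SingularDesignError, match="a"):
            fit_mnr(rng.standard_normal(10), design)

    def test_needs_more_rows_than_columns(self, rng):
        design = _full_rank_design(4, 4, rng)
        with pytest.raises(InvalidInputError):
            fit_mnr(rng.standard_normal(4), design)


class TestFitLocal:
    def test_uniform_weights_reduce_to_global_fit(self, small_fits):
        data, mnr, _ = small_fits
        w = np.ones(data.n)
        for i in (0, data.n // 2, data.n - 1):
            eta_i, _, _ = fit_local(data.y, mnr.design, w, i)
            np.testing.assert_allclose(eta_i, mnr.eta, atol=1e-8)

    def test_constant_response_reproduced_exactly(self, small_fits, rng):
        data, mnr, _ = small_fits
        c = 4.2
        w = rng.uniform(0.1, 1.0, data.n)
        _, yhat, _ = fit_local(np.full(data.n, c), mnr.design, w, 3)
        assert yhat == pytest.approx(c, abs=1e-8)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        # brute force (Q'WQ)^-1 Q'W y with an explicit inverse
        design = _full_rank_design(10, 4, rng)
        y = rng.standard_normal(10)
        w = rng.uniform(0.2, 2.0, 10)
        eta_i, yhat_i, g_row = fit_local(y, design, w, 6)
        Q, W = design.values, np.diag(w)
        eta_oracle = np.linalg.inv(Q.T @ W @ Q) @ Q.T @ W @ y
        np.testing.assert_allclose(eta_i, eta_oracle, atol=1e-8)
        np.testing.assert_allclose(g_row, Q[6] @ np.linalg.inv(Q.T @ W @ Q) @ Q.T @ W, atol=1e-8)
        assert yhat_i == pytest.approx(g_row @ y)


class TestFitGwnr:
    def test_uniform_weight_limit_equals_global(self, small_data, uniform_spec):
        data, _ = small_data
        gwnr = fit_gwnr(data, uniform_spec)
        mnr = fit_mnr(data.y, gwnr.design)
        np.testing.assert_allclose(gwnr.G, mnr.L, atol=1e-8)
        assert gwnr.sse == pytest.approx(mnr.sse, rel=1e-10)

    def test_sse_matches_per_location_loop_oracle(self, small_fits, small_scenario):
        data, _, gwnr = small_fits
        d = pairwise_distance(data.coords)
        sse = 0.0
        for i in range(data.n):
            w = kernel_weights(d[i], small_scenario.spec.weights, location=i)
            _, yhat_i, _ = fit_local(data.y, gwnr.design, w, i)
            sse += (data.y[i] - yhat_i) ** 2
        assert gwnr.sse == pytest.approx(sse, rel=1e-10)

    def test_fitted_and_residual_identities(self, small_fits):
        data, _, gwnr = small_fits
        np.testing.assert_allclose(gwnr.fitted, gwnr.G @ data.y, atol=1e-12)
        np.testing.assert_allclose(gwnr.residuals, data.y - gwnr.fitted, atol=1e-12)
        assert gwnr.sse == pytest.approx(float(gwnr.residuals @ gwnr.residuals))

    def test_hat_matrix_row_sums_are_one(self, small_fits):
        # the intercept lies in every local basis, so G reproduces constants
        _, _, gwnr = small_fits
        np.testing.assert_allclose(gwnr.G @ np.ones(gwnr.G.shape[0]), 1.0, atol=1e-8)

    def test_constant_response_zero_sse(self, small_scenario, small_data):
        data, _ = small_data
        data_c = replace(data, y=np.full(data.n, 2.5))
        gwnr = fit_gwnr(data_c, small_scenario.spec)
        assert gwnr.sse == pytest.approx(0.0, abs=1e-16)

    def test_gamma1_in_uniform_limit_is_residual_df(self, small_data, uniform_spec):
        data, _ = small_data
        gwnr = fit_gwnr(data, uniform_spec)
        gamma1 = gwnr.sse / gwnr.sigma2_hat
        assert gamma1 == pytest.approx(data.n - expected_rank(gwnr.design), abs=1e-6)

    def test_sse_unbiasedness_small_monte_carlo(self):
        # E(SSE) = sigma^2 * gamma1 under the null; quick 100-rep check
        from gwnr.simulate import mc_run

        scn = SimulationScenario(n=40, seed=5)
        res = mc_run(scn, 100)
        se = res.sse_gwnr.std(ddof=1) / np.sqrt(res.sse_gwnr.size)
        assert abs(res.sse_gwnr.mean() - res.gamma1.mean()) < 3 * se
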