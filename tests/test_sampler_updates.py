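"""Conditional updates checked against closed forms and numerical oracles."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

from mirnorm._truncnorm import sample_lower_truncated, sample_upper_truncated
from mirnorm.model import DOWN, NULL, UP, HyperState, ModelState, PriorConstants
from mirnorm.sampler import (_mh_accept, delta_component_logweights, impute_censored,
                             update_array_effects, update_delta_mixture,
                             update_gene_effects, update_hyperparameters,
                             update_variances)

from conftest import make_data


def _hyper(**kw):
    defaults = dict(g_mean=0.0, s2=100.0, mu=-1.8, eta2=1.0,
                    xi=np.array([1 / 3, 1 / 3, 1 / 3]),
                    mu_plus=1.0, sigma2_plus=0.25, mu_minus=-1.0, sigma2_minus=0.25)
    defaults.update(kw)
    return HyperState(**defaults)


def _null_state(g, a, y, sigma2=1.0, alpha=None):
    return ModelState(alpha=np.zeros(g) if alpha is None else np.asarray(alpha, float),
                      delta=np.zeros(g), z=np.full(g, NULL, dtype=np.int8),
                      sigma2=np.full(g, sigma2), a0=np.zeros(a), a1=np.zeros(a),
                      y_complete=np.asarray(y, dtype=float))


class TestTruncatedNormalSampler:
    def test_half_normal_mean(self, rng):
        """TN(0, 1, upper=0) has mean -sqrt(2/pi) ~ -0.79788."""
        draws = sample_upper_truncated(rng, np.zeros(100_000), 1.0, 0.0)
        assert draws.max() <= 0.0
        assert draws.mean() == pytest.approx(-np.sqrt(2 / np.pi), abs=0.01)

    def test_extreme_bound_stays_finite_and_bounded(self, rng):
        draws = sample_upper_truncated(rng, np.zeros(10_000), 1.0, -10.0)
        assert np.all(np.isfinite(draws))
        assert np.all(draws <= -10.0)

    def test_lower_truncation_mirrors_upper(self):
        d1 = sample_lower_truncated(np.random.default_rng(5), 2.0, 3.0, 0.0)
        assert np.all(np.asarray(d1) >= 0.0)
        # distributional mirror: mean of -X truncated above matches
        rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
        lo = sample_lower_truncated(rng_a, np.full(50_000, 1.0), 2.0, 0.0)
        up = sample_upper_truncated(rng_b, np.full(50_000, -1.0), 2.0, 0.0)
        assert lo.mean() == pytest.approx(-up.mean(), abs=0.03)


class TestImputation:
    def test_draws_respect_detection_limits(self, rng):
        censored = rng.random((20, 4)) < 0.4
        vals = rng.normal(3, 1, size=(20, 4))
        data = make_data(vals, condition=[1, 1, 2, 2], censored=censored,
                         detection_limit=np.array([2.0, 2.5, 1.5, 3.0]))
        state = _null_state(20, 4, np.nan_to_num(data.values, nan=0.0), alpha=vals.mean(axis=1))
        hyper = _hyper()
        for _ in range(5):
            impute_censored(state, hyper, data, rng)
            lims = np.broadcast_to(data.detection_limit, (20, 4))
            assert np.all(state.y_complete[censored] <= lims[censored])

    def test_untouched_cells_remain_untouched(self, rng):
        censored = np.zeros((5, 4), dtype=bool)
        censored[0, 1] = True
        vals = rng.normal(3, 1, size=(5, 4))
        data = make_data(vals, condition=[1, 1, 2, 2], censored=censored,
                         detection_limit=np.full(4, 2.0))
        state = _null_state(5, 4, np.nan_to_num(data.values, nan=0.0))
        before = state.y_complete.copy()
        impute_censored(state, _hyper(), data, rng)
        assert np.array_equal(state.y_complete[~censored], before[~censored])
        assert state.y_complete[0, 1] <= 2.0

    def test_nonfinite_parameters_name_the_cell(self, rng):
        censored = np.zeros((2, 4), dtype=bool)
        censored[1, 2] = True
        vals = rng.normal(3, 1, size=(2, 4))
        data = make_data(vals, condition=[1, 1, 2, 2], censored=censored,
                         detection_limit=np.full(4, 2.0),
                         gene_ids=["gA", "gB"], array_ids=["a", "b", "c", "d"])
        state = _null_state(2, 4, np.nan_to_num(data.values, nan=0.0))
        state.alpha[1] = np.nan
        with pytest.raises(ValueError, match="gene 'gB'.*array 'c'"):
            impute_censored(state, _hyper(), data, rng)


class TestGeneEffects:
    def test_flat_prior_limit_is_sample_mean(self, rng):
        """With a0=a1=0, delta=0, sigma2=1 and a vague prior, the conditional
        centers on the gene-wise mean of the observations."""
        y = np.tile([1.0, 2.0, 3.0, 2.0], (50_000, 1))
        data = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(50_000, 4, y)
        hyper = _hyper(s2=1e6)
        update_gene_effects(state, hyper, data, rng)
        assert state.alpha.mean() == pytest.approx(2.0, abs=0.01)

    def test_dogmatic_prior_limit(self, rng):
        y = np.tile([1.0, 2.0, 3.0, 2.0], (1000, 1))
        data = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(1000, 4, y)
        hyper = _hyper(g_mean=7.0, s2=1e-12)
        update_gene_effects(state, hyper, data, rng)
        assert np.allclose(state.alpha, 7.0, atol=1e-4)

    def test_draws_match_grid_normalized_conditional(self, rng):
        """KS test of sampled alphas against the numerically integrated
        full conditional on a random 1-gene instance."""
        y_row = rng.normal(2.0, 0.8, size=4)
        a0 = np.array([0.2, -0.2, 0.3, -0.3])
        a1 = np.array([0.1, -0.1, 0.05, -0.05])
        delta, sigma2 = 0.6, 0.7
        g = 10_000
        y = np.tile(y_row, (g, 1))
        data = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(g, 4, y, sigma2=sigma2)
        state.delta[:] = delta
        state.z[:] = UP
        state.a0, state.a1 = a0, a1
        hyper = _hyper(g_mean=1.0, s2=4.0)
        update_gene_effects(state, hyper, data, rng)

        grid = np.linspace(-3, 7, 20_001)
        sign = np.where(data.condition == 2, 1.0, -1.0)
        log_dens = np.zeros_like(grid)
        for a in range(4):
            m = grid * (1 + a0[a]) + sign[a] * delta / 2 + a1[a]
            log_dens += stats.norm.logpdf(y_row[a], m, np.sqrt(sigma2))
        log_dens += stats.norm.logpdf(grid, 1.0, 2.0)
        dens = np.exp(log_dens - log_dens.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        ks = stats.kstest(state.alpha, lambda x: np.interp(x, grid, cdf))
        assert ks.pvalue > 0.01

    def test_zero_precision_rejected(self, rng, toy_data):
        state = _null_state(2, 4, toy_data.values)
        state.sigma2[:] = np.inf
        hyper = _hyper()
        hyper.s2 = np.inf  # bypass validation to exercise the guard
        with pytest.raises(ValueError, match="precision"):
            update_gene_effects(state, hyper, toy_data, rng)


class TestDeltaMixture:
    def test_degenerate_weights_give_all_null(self, rng, toy_data):
        state = _null_state(2, 4, toy_data.values)
        hyper = _hyper(xi=np.array([1.0, 0.0, 0.0]))
        update_delta_mixture(state, hyper, toy_data, rng)
        assert np.all(state.z == NULL)
        assert np.all(state.delta == 0.0)

    def test_symmetry_gives_equal_up_down_weights(self):
        """Zero between-condition residual difference + symmetric hypers."""
        y = np.tile([1.0, -1.0, 1.0, -1.0], (3, 1))  # same pattern in both conditions
        data = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(3, 4, y)
        hyper = _hyper(mu_plus=0.9, mu_minus=-0.9, sigma2_plus=0.3, sigma2_minus=0.3,
                       xi=np.array([0.4, 0.3, 0.3]))
        logw, _ = delta_component_logweights(state, hyper, data)
        assert np.allclose(logw[:, 1], logw[:, 2], atol=1e-12)

    def test_weights_match_quadrature_oracle(self, rng):
        """1 gene, 5+5 arrays, sigma2=0.01, residual difference 2.0."""
        sigma2 = 0.01
        cond = np.repeat([1, 2], 5)
        y = np.where(cond == 2, 1.0, -1.0) + rng.normal(0, np.sqrt(sigma2), 10) * 0
        y = y[None, :]  # exact residual difference of 2.0
        data = make_data(y, condition=cond)
        state = _null_state(1, 10, y, sigma2=sigma2)
        hyper = _hyper(xi=np.array([0.5, 0.25, 0.25]))
        logw, _ = delta_component_logweights(state, hyper, data)
        w = np.exp(logw[0] - logsumexp(logw[0]))

        sign = np.where(cond == 2, 1.0, -1.0)

        def lik_ratio(d):
            return np.exp(-np.sum((y[0] - sign * d / 2) ** 2) / (2 * sigma2)
                          + np.sum(y[0] ** 2) / (2 * sigma2))

        sd = 0.5
        z_plus = stats.norm.cdf(hyper.mu_plus / sd)
        z_minus = stats.norm.cdf(-hyper.mu_minus / sd)
        i_up = integrate.quad(lambda d: lik_ratio(d) * stats.norm.pdf(d, 1.0, sd) / z_plus,
                              0, 10, limit=400)[0]
        i_dn = integrate.quad(lambda d: lik_ratio(d) * stats.norm.pdf(d, -1.0, sd) / z_minus,
                              -10, 0, limit=400)[0]
        oracle = np.array([0.5, 0.25 * i_up, 0.25 * i_dn])
        oracle /= oracle.sum()
        assert np.allclose(w, oracle, rtol=1e-6)

    def test_drawn_deltas_respect_component_sign(self, rng):
        data, _ = _strong_signal_data(rng)
        state = _null_state(data.n_genes, data.n_arrays, data.values,
                            alpha=data.values.mean(axis=1))
        hyper = _hyper()
        for _ in range(20):
            update_delta_mixture(state, hyper, data, rng)
            assert np.all(state.delta[state.z == NULL] == 0.0)
            assert np.all(state.delta[state.z == UP] > 0.0)
            assert np.all(state.delta[state.z == DOWN] < 0.0)


def _strong_signal_data(rng, g=20):
    cond = np.repeat([1, 2], 3)
    sign = np.where(cond == 2, 1.0, -1.0)
    delta = np.zeros(g)
    delta[: g // 4] = 2.0
    delta[g // 4: g // 2] = -2.0
    y = 5.0 + 0.5 * np.outer(delta, sign) + rng.normal(0, 0.2, (g, 6))
    return make_data(y, condition=cond), delta


class TestVarianceUpdate:
    def test_mh_ratio_one_always_accepts(self, rng):
        assert np.all(_mh_accept(rng, np.zeros(10_000)))

    def test_prior_reproduction_with_no_observations(self, rng):
        """Genes with no attached data: stationary draws follow logNormal(-1.8, 1)."""
        g = 200
        state = _null_state(g, 4, np.zeros((g, 4)), sigma2=0.2)
        hyper = _hyper(mu=-1.8, eta2=1.0)
        draws = []
        for it in range(3000):
            update_variances(state, hyper, None, rng, step=1.0)
            if it >= 500:
                draws.append(np.log(state.sigma2))
        draws = np.concatenate(draws)
        assert draws.mean() == pytest.approx(-1.8, abs=0.05)
        assert draws.std() == pytest.approx(1.0, abs=0.05)

    def test_posterior_consistency_large_n(self, rng):
        true_var = 0.37
        n = 10_000
        cond = np.repeat([1, 2], n // 2)
        y = rng.normal(0, np.sqrt(true_var), size=(1, n))
        data = make_data(y, condition=cond)
        state = _null_state(1, n, y)
        hyper = _hyper()
        for _ in range(300):
            update_variances(state, hyper, data, rng, step=0.05)
        assert state.sigma2[0] == pytest.approx(true_var, rel=0.05)


class TestArrayEffects:
    def test_constraints_hold_on_every_draw(self, rng):
        data, _ = _strong_signal_data(rng)
        state = _null_state(data.n_genes, data.n_arrays, data.values,
                            alpha=data.values.mean(axis=1))
        const = PriorConstants()
        for _ in range(50):
            update_array_effects(state, _hyper(), data, rng, const)
            for c in (1, 2):
                idx = data.arrays_in_condition(c)
                assert abs(state.a0[idx].mean()) < 1e-10
                assert abs(state.a1[idx].mean()) < 1e-10

    def test_zero_residuals_center_draws_at_zero(self, rng):
        g, a = 100, 4
        alpha = rng.uniform(1, 9, g)
        y = np.tile(alpha[:, None], (1, a))  # exactly alpha, no array effect, no noise
        data = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(g, a, y, sigma2=1.0, alpha=alpha)
        draws = []
        for _ in range(500):
            update_array_effects(state, _hyper(), data, rng, PriorConstants())
            draws.append(np.concatenate([state.a0, state.a1]))
        means = np.mean(draws, axis=0)
        assert np.allclose(means, 0.0, atol=0.05)

    def test_two_replicates_are_antisymmetric(self, rng):
        data, _ = _strong_signal_data(rng)
        y = data.values[:, [0, 1, 3, 4]]
        data2 = make_data(y, condition=[1, 1, 2, 2])
        state = _null_state(data2.n_genes, 4, y, alpha=y.mean(axis=1))
        for _ in range(10):
            update_array_effects(state, _hyper(), data2, rng, PriorConstants())
            assert state.a0[0] == pytest.approx(-state.a0[1], abs=1e-12)
            assert state.a1[2] == pytest.approx(-state.a1[3], abs=1e-12)


class TestHyperparameterUpdates:
    def _state_with_z(self, rng, counts=(60, 20, 20)):
        g = sum(counts)
        z = np.concatenate([np.full(counts[0], NULL), np.full(counts[1], UP),
                            np.full(counts[2], DOWN)]).astype(np.int8)
        delta = np.concatenate([np.zeros(counts[0]),
                                rng.uniform(0.5, 1.5, counts[1]),
                                -rng.uniform(0.5, 1.5, counts[2])])
        state = _null_state(g, 4, np.zeros((g, 4)), sigma2=0.2)
        state.z, state.delta = z, delta
        state.alpha = rng.uniform(0, 10, g)
        return state

    def test_dirichlet_posterior_mean(self, rng):
        state = self._state_with_z(rng)
        const = PriorConstants()
        xi_draws = []
        for _ in range(4000):
            hyper = _hyper()
            update_hyperparameters(state, hyper, const, rng)
            xi_draws.append(hyper.xi)
        means = np.mean(xi_draws, axis=0)
        expected = np.array([61, 21, 21]) / 103
        # 3 MC standard errors on i.i.d. Dirichlet draws
        se = np.sqrt(expected * (1 - expected) / 104) / np.sqrt(4000)
        assert np.all(np.abs(means - expected) < 3 * se + 1e-3)

    def test_all_null_counts(self, rng):
        state = self._state_with_z(rng, counts=(40, 0, 0))
        const = PriorConstants()
        xi_draws = []
        for _ in range(2000):
            hyper = _hyper()
            update_hyperparameters(state, hyper, const, rng)
            xi_draws.append(hyper.xi)
        means = np.mean(xi_draws, axis=0)
        expected = np.array([41, 1, 1]) / 43
        assert np.all(np.abs(means - expected) < 0.01)

    def test_degenerate_conjugate_limit_for_gene_mean(self, rng):
        state = self._state_with_z(rng, counts=(50, 0, 0))
        state.alpha = np.full(50, 3.0)
        const = PriorConstants()
        hyper = _hyper()
        draws = []
        for _ in range(200):
            update_hyperparameters(state, hyper, const, rng)
            draws.append(hyper.g_mean)
        assert np.mean(draws) == pytest.approx(3.0, abs=0.01)

    def test_empty_component_samples_from_prior_support(self, rng):
        state = self._state_with_z(rng, counts=(40, 0, 0))
        const = PriorConstants()
        hyper = _hyper()
        for _ in range(50):
            update_hyperparameters(state, hyper, const, rng)
            assert hyper.mu_plus > 0
            assert hyper.mu_minus < 0
            assert hyper.sigma2_plus > 0
            assert hyper.sigma2_minus > 0
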