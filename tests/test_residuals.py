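import numpy as np
import pytest
from scipy import integrate, stats

from teppld.residuals import (
    FitError,
    WeibullFit,
    conditional_mean_beyond,
    fit_weibull_censored,
    ote_residuals,
    standardize,
    weibull_mean,
)
from teppld.simulator import Cohort, draw_observation_age, get_model, simulate_cohort


def _weibull_censored_sample(k, lam, n, rng):
    t_event = lam * rng.weibull(k, n)
    t_obs = draw_observation_age(n, rng)
    event = (t_event < t_obs).astype(int)
    return np.where(event == 1, t_event, t_obs), event


class TestWeibullFit:
    def test_parameter_recovery_large_n(self, rng):
        t, e = _weibull_censored_sample(2.0, 15.0, 2000, rng)
        fit = fit_weibull_censored(t, e)
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.scale == pytest.approx(15.0, rel=0.05)
        assert fit.n_events + fit.n_censored == 2000

    def test_uncensored_fit_matches_scipy_mle(self, rng):
        t = 12.0 * rng.weibull(1.8, 500)
        fit = fit_weibull_censored(t, np.ones_like(t, dtype=int))
        k_ref, _, lam_ref = stats.weibull_min.fit(t, floc=0)
        assert fit.shape == pytest.approx(k_ref, rel=1e-3)
        assert fit.scale == pytest.approx(lam_ref, rel=1e-3)

    def test_too_few_events_rejected(self):
        with pytest.raises(FitError):
            fit_weibull_censored([5.0, 6.0, 7.0], [0, 0, 0])
        with pytest.raises(FitError):
            fit_weibull_censored([5.0, 6.0, 7.0], [1, 0, 0])

    def test_nonpositive_times_rejected(self):
        with pytest.raises(FitError):
            fit_weibull_censored([0.0, 6.0, 7.0], [1, 1, 1])


class TestWeibullMean:
    def test_exponential_mean_is_scale(self):
        assert weibull_mean(WeibullFit(1.0, 15.0)) == pytest.approx(15.0)

    def test_gamma_function_value(self):
        assert weibull_mean(WeibullFit(2.0, 1.0)) == pytest.approx(0.8862269, abs=1e-6)

    def test_matches_survival_integral(self):
        fit = WeibullFit(2.7, 13.0)
        s = lambda t: np.exp(-((t / fit.scale) ** fit.shape))
        ref, _ = integrate.quad(s, 0, np.inf)
        assert weibull_mean(fit) == pytest.approx(ref, rel=1e-6)


class TestConditionalMeanBeyond:
    def test_unconditional_limit_at_zero(self):
        fit = WeibullFit(2.0, 15.0)
        assert conditional_mean_beyond(fit, 0.0) == pytest.approx(weibull_mean(fit))

    def test_exponential_memorylessness(self):
        assert conditional_mean_beyond(WeibullFit(1.0, 15.0), 10.0) == pytest.approx(25.0, rel=1e-9)

    def test_matches_quadrature_oracle(self):
        fit = WeibullFit(2.0, 15.0)
        c = 20.0
        s = lambda t: np.exp(-((t / fit.scale) ** fit.shape))
        tail, _ = integrate.quad(s, c, np.inf)
        ref = c + tail / s(c)
        assert conditional_mean_beyond(fit, c) == pytest.approx(ref, rel=1e-6)

    def test_nondecreasing_in_threshold(self):
        fit = WeibullFit(1.6, 12.0)
        cs = np.linspace(0, 60, 40)
        vals = [conditional_mean_beyond(fit, c) for c in cs]
        assert np.all(np.diff(vals) >= -1e-9)
        assert all(v >= c for v, c in zip(vals, cs))

    def test_saturates_when_survival_underflows(self):
        fit = WeibullFit(3.0, 10.0)
        assert conditional_mean_beyond(fit, 1e6) == 1e6

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            conditional_mean_beyond(WeibullFit(2.0, 15.0), -1.0)


class TestOTEResiduals:
    def test_uncensored_residual_is_exact_difference(self, rng):
        n = 300
        t = 12.0 * rng.weibull(2.0, n)
        cohort = Cohort(
            sample_id=np.arange(n),
            genotype=rng.integers(0, 3, n),
            covariate=np.where(np.arange(n) < n // 2, 1, 2),
            time=t,
            event=np.ones(n, dtype=int),
        )
        res = ote_residuals(cohort, stratify_on_covariate=True)
        for y in (1, 2):
            mask = cohort.covariate == y
            mu = weibull_mean(res.source_fits[y])
            np.testing.assert_allclose(res.values[mask], t[mask] - mu, rtol=0, atol=1e-12)

    def test_censored_residual_exceeds_censoring_difference(self, null_cohort):
        res = ote_residuals(null_cohort)
        for y in (1, 2):
            mask = (null_cohort.covariate == y) & (null_cohort.event == 0)
            mu = weibull_mean(res.source_fits[y])
            assert np.all(res.values[mask] > null_cohort.time[mask] - mu)

    def test_stratum_residual_means_near_zero_under_null(self):
        # under the fitted distribution E[residual] = 0 exactly; fitting a
        # Weibull to truncated-normal ages leaves only a small misspecification
        # offset, well under 1% of the phenotype SD (3.4 years)
        means = {1: [], 2: []}
        for r in range(60):
            c = simulate_cohort(get_model("M1"), 400, seed=4000 + r)
            res = ote_residuals(c)
            for y in (1, 2):
                means[y].append(res.values[c.covariate == y].mean())
        for y in (1, 2):
            m = np.asarray(means[y])
            assert abs(m.mean()) < 0.034

    def test_pooled_fit_option(self, null_cohort):
        res = ote_residuals(null_cohort, stratify_on_covariate=False)
        assert set(res.source_fits) == {"pooled"}
        assert res.values.shape == (len(null_cohort),)


class TestStandardize:
    def test_unit_moments_and_idempotence(self, null_cohort):
        res = standardize(ote_residuals(null_cohort))
        assert abs(res.values.mean()) < 1e-8
        assert abs(res.values.std() - 1.0) < 1e-8
        assert res.standardized
        again = standardize(res)
        np.testing.assert_allclose(again.values, res.values, atol=1e-12)

    def test_constant_input_rejected(self):
        from teppld.residuals import ResidualPhenotype

        with pytest.raises(ValueError):
            standardize(ResidualPhenotype(values=np.ones(10)))
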