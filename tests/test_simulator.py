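import numpy as np
import pytest
from scipy import stats

from teppld.simulator import (
    MODELS,
    GeneratingModel,
    cell_distribution,
    draw_covariates,
    draw_genotypes,
    draw_observation_age,
    get_model,
    match_moments,
    sample_chip_maf,
    simulate_cohort,
)


class TestGenotypes:
    @pytest.mark.parametrize("maf", [0.1, 0.3, 0.5])
    def test_hwe_frequencies_at_large_n(self, maf, rng):
        n = 1_000_000
        g = draw_genotypes(n, maf, rng)
        for k, p in enumerate([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(g == k) - p) < 3 * se

    def test_degenerate_frequency_gives_all_major(self, rng):
        assert np.all(draw_genotypes(100, 0.0, rng) == 0)

    def test_maf_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_genotypes(10, 0.6, rng)
        with pytest.raises(ValueError):
            draw_genotypes(0, 0.3, rng)

    def test_zero_homozygote_class_probability(self, rng):
        # P(no minor-allele homozygote among 400 at MAF 0.1) = (1 - 0.01)^400
        expected = (1 - 0.01) ** 400
        reps = 3000
        zeros = sum(np.all(draw_genotypes(400, 0.1, rng) != 2) for _ in range(reps))
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(zeros / reps - expected) < 3 * se


class TestCovariates:
    def test_fixed_law_splits_half_and_half(self, rng):
        y = draw_covariates(400, "fixed", rng)
        assert np.sum(y == 1) == 200 and np.sum(y == 2) == 200
        y = draw_covariates(5, "fixed", rng)
        assert np.sum(y == 1) == 2  # floor(n/2)

    def test_random_law_centers_on_seventy_percent(self, rng):
        fracs = [np.mean(draw_covariates(50, "random", rng) == 2) for _ in range(2000)]
        # per-replicate variance = alpha spread + binomial noise
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.7) < 3 * se

    def test_single_draw_valid(self, rng):
        assert draw_covariates(1, "random", rng)[0] in (1, 2)


class TestCellDistribution:
    def test_null_cell_is_anchor_normal(self):
        d = cell_distribution(get_model("M1"), 1, 1)
        assert d.mean() == pytest.approx(11.6, abs=0.01)  # truncation at 0 is a 3.4-sigma event
        assert d.std() == pytest.approx(3.4, abs=0.01)

    def test_additive_cell_arithmetic(self):
        # genotype 2, y=2: 11.6 + 3.4*0.5 + 3 = 16.3
        mu, sd = get_model("M2").cell_mean_sd_years(2, 2)
        assert mu == pytest.approx(16.3)
        assert sd == pytest.approx(3.4)

    def test_explicit_covariate_cells_have_no_extra_offset(self):
        mu, sd = get_model("M8").cell_mean_sd_years(0, 2)
        assert mu == pytest.approx(11.6 + 3.4 * 1.26)
        assert sd == pytest.approx(3.4 * 2)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            get_model("M1").replace(family="LN")

    @pytest.mark.parametrize("family", ["WB", "BS", "GM"])
    def test_non_normal_cells_match_normal_moments(self, family):
        model = get_model("M2", family=family)
        for g in (0, 1, 2):
            for y in (1, 2):
                mu, sd = model.cell_mean_sd_years(g, y)
                d = cell_distribution(model, g, y)
                m, v = d.stats(moments="mv")
                assert m == pytest.approx(mu, rel=1e-6)
                assert np.sqrt(v) == pytest.approx(sd, rel=1e-6)


class TestMomentMatching:
    def test_gamma_closed_form(self):
        mm = match_moments("GM", 11.6, 3.4)
        assert mm.params["shape"] == pytest.approx(11.640, abs=5e-4)
        assert mm.params["scale"] == pytest.approx(0.9966, abs=5e-5)

    def test_weibull_cv_one_is_exponential(self):
        mm = match_moments("WB", 7.0, 7.0)
        assert mm.params["shape"] == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("family", ["WB", "BS", "GM"])
    @pytest.mark.parametrize("mean,sd", [(11.6, 3.4), (16.3, 5.1), (8.2, 1.7), (14.6, 6.8)])
    def test_round_trip(self, family, mean, sd):
        d = match_moments(family, mean, sd).dist
        m, v = d.stats(moments="mv")
        assert m == pytest.approx(mean, rel=1e-6)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            match_moments("WB", -1.0, 2.0)
        with pytest.raises(ValueError):
            match_moments("XX", 10.0, 2.0)


class TestObservationAge:
    def test_moments_and_support(self, rng):
        draws = draw_observation_age(1_000_000, rng)
        assert np.all(draws > 0)
        # mean r(1-p)/p = 15, var r(1-p)/p^2 = 37.5 (zero-redraw shift is ~1e-3)
        assert np.mean(draws) == pytest.approx(15.0, abs=3 * np.sqrt(37.5 / 1e6) + 2e-3)
        assert np.var(draws) == pytest.approx(37.5, rel=0.02)


class TestSimulateCohort:
    def test_bit_reproducible(self):
        a = simulate_cohort(get_model("M2"), 100, seed=7)
        b = simulate_cohort(get_model("M2"), 100, seed=7)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.genotype, b.genotype)
        assert np.array_equal(a.event, b.event)
        c = simulate_cohort(get_model("M2"), 100, seed=8)
        assert not np.array_equal(a.time, c.time)

    def test_null_censoring_rate_near_forty_percent(self):
        fracs = [
            1 - simulate_cohort(get_model("M1"), 400, seed=3000 + r).event.mean()
            for r in range(400)
        ]
        assert 0.38 < np.mean(fracs) < 0.44

    def test_genotype_independent_of_phenotype_under_null(self):
        cors = []
        for r in range(100):
            c = simulate_cohort(get_model("M1"), 400, seed=6000 + r)
            cors.append(np.corrcoef(c.genotype, c.time)[0, 1])
        assert abs(np.mean(cors)) < 3 * np.std(cors) / np.sqrt(len(cors))

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_cohort(get_model("M1"), 1, seed=0)

    @pytest.mark.parametrize("family", ["WB", "BS", "GM"])
    def test_alternative_families_run(self, family):
        c = simulate_cohort(get_model("M3", family=family), 200, seed=1)
        assert np.all(c.time > 0)
        assert 0 < c.event.mean() < 1


class TestChipMAF:
    def test_matches_array_spectrum_moments(self, rng):
        draws = sample_chip_maf(1_000_000, rng)
        assert np.min(draws) >= 0.03 and np.max(draws) <= 0.5
        assert np.mean(draws) == pytest.approx(0.23, abs=0.001)
        assert np.std(draws) == pytest.approx(0.14, abs=0.001)


def test_model_registry_invariants():
    assert set(MODELS) == {f"M{i}" for i in range(1, 9)} | {f"Epi{i}" for i in range(1, 8)}
    for model in MODELS.values():
        assert np.all(model.std_sds > 0)
        if model.model_id in ("M1", "M2", "M3", "M4", "M5", "M6", "M7"):
            # same standard-scale cells in both covariate groups, offset in years
            assert np.array_equal(model.std_means[:, 0], model.std_means[:, 1])
            assert model.covariate_offset_years == 3.0
    assert MODELS["M8"].covariate_offset_years == 0.0
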