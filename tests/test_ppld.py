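import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from teppld.ppld import (
    PI,
    PPLDConfig,
    PriorSpec,
    TraitModelPoint,
    bayes_ratio,
    log_lr,
    ppld_from_br,
    scan,
    sequential_update,
)
from teppld.residuals import ote_residuals, standardize
from teppld.simulator import get_model, simulate_cohort

from conftest import mc_prior_average_lr


class TestLogLR:
    def test_equal_parameters_collapse_to_null(self, rng):
        gamma = TraitModelPoint(0.2, 0.2, 0.2, 1.1, 1.1, 1.1)
        t = rng.normal(size=50)
        g = rng.integers(0, 3, 50)
        assert log_lr(gamma, t, g, np.array([0.25, 0.5, 0.25])) == pytest.approx(0.0, abs=1e-12)

    def test_two_individual_hand_example(self):
        # t = (-1, 1), g = (0, 2), additive means (-1, 0, 1), unit SDs:
        # per-individual ratio phi(0) / (0.25 phi(0) + 0.5 phi(1) + 0.25 phi(2))
        gamma = TraitModelPoint(-1, 0, 1, 1, 1, 1)
        freqs = np.array([0.25, 0.5, 0.25])
        got = np.exp(log_lr(gamma, np.array([-1.0, 1.0]), np.array([0, 2]), freqs))
        r1 = norm.pdf(0) / (0.25 * norm.pdf(0) + 0.5 * norm.pdf(1) + 0.25 * norm.pdf(2))
        assert got == pytest.approx(r1 * r1, rel=1e-10)
        assert got == pytest.approx(2.90, rel=2e-3)

    def test_mirror_symmetry(self, rng):
        t = rng.normal(size=40)
        g = rng.integers(0, 3, 40)
        freqs = np.array([0.36, 0.48, 0.16])
        # negating the phenotype sends phi(t; mu, sd) to phi(-t; -mu, sd), so the
        # relabeled groups carry negated, order-reversed means
        gamma = TraitModelPoint(-0.7, 0.1, 0.9, 0.8, 1.0, 1.3)
        mirrored = TraitModelPoint(-0.9, -0.1, 0.7, 1.3, 1.0, 0.8)
        a = log_lr(gamma, t, g, freqs)
        b = log_lr(mirrored, -t, 2 - g, freqs[::-1])
        assert a == pytest.approx(b, abs=1e-10)

    def test_nonfinite_phenotype_rejected(self):
        gamma = TraitModelPoint(0, 0, 0, 1, 1, 1)
        with pytest.raises(ValueError):
            log_lr(gamma, np.array([np.nan, 1.0]), np.array([0, 1]), np.array([0.25, 0.5, 0.25]))


class TestPPLDTransform:
    def test_evidence_parity_gives_prior(self):
        assert ppld_from_br(1.0) == PI

    def test_limits(self):
        assert ppld_from_br(0.0) == 0.0
        assert ppld_from_br(1e18) == pytest.approx(1.0, abs=1e-10)

    def test_algebraic_inversion_at_half(self):
        assert ppld_from_br((1 - PI) / PI) == pytest.approx(0.5, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ppld_from_br(-0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_monotone_in_br(self, a, b):
        lo, hi = sorted((a, b))
        assert ppld_from_br(lo) <= ppld_from_br(hi)


class TestBayesRatio:
    def test_monomorphic_snp_is_evidence_neutral(self, rng):
        t = rng.normal(size=100)
        res = bayes_ratio(t, np.zeros(100, dtype=int))
        assert res.br == 1.0
        assert res.ppld == pytest.approx(PI)
        assert res.diagnostics["monomorphic"]

    def test_quadrature_matches_monte_carlo_oracle(self, rng):
        for trial in range(6):
            n = int(rng.integers(8, 21))
            g = rng.integers(0, 3, n)
            t = rng.normal(0, 1, n) + 0.4 * (g - 1)
            t = (t - t.mean()) / t.std()
            f = g.mean() / 2
            freqs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            br_mc, se_mc = mc_prior_average_lr(t, g, freqs, seed=900 + trial)
            res = bayes_ratio(t, g, genotype_freqs=freqs)
            se = np.sqrt(se_mc**2 + (res.br * res.diagnostics["rel_se"]) ** 2)
            assert abs(res.br - br_mc) < 3 * se

    def test_permutation_null_pulls_log_br_negative(self, additive_cohort, rng):
        resid = standardize(ote_residuals(additive_cohort))
        vals = []
        for _ in range(30):
            perm = rng.permutation(len(additive_cohort))
            vals.append(bayes_ratio(resid.values, additive_cohort.genotype[perm]).log10br)
        assert np.median(vals) < 0

    def test_genotype_relabel_symmetry(self, rng):
        n = 200
        g = rng.integers(0, 3, n)
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n) + 0.3 * g)
        a = bayes_ratio(t, g)
        b = bayes_ratio(t, 2 - g)
        se = abs(a.log10br) * 0 + (a.diagnostics["rel_se"] + b.diagnostics["rel_se"]) / np.log(10)
        assert a.log10br == pytest.approx(b.log10br, abs=3 * se + 0.05)

    def test_means_only_point_sd_equals_reduced_integration(self, rng):
        # collapsing the SD box to the point {1} must agree with integrating
        # the same integrand over the three means only (grid cross-check)
        n = 30
        g = rng.integers(0, 3, n)
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n))
        prior = PriorSpec(sd_bounds=(1.0, 1.0), means_only=True)
        is_res = bayes_ratio(t, g, prior, PPLDConfig(n_points=16384))
        grid_res = bayes_ratio(t, g, prior, PPLDConfig(method="grid", grid_nodes_mean=40))
        rel = 3 * is_res.diagnostics["rel_se"] + 0.02
        assert is_res.br == pytest.approx(grid_res.br, rel=rel)

    def test_shared_sd_mode_runs(self, rng):
        n = 60
        g = rng.integers(0, 3, n)
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n))
        res = bayes_ratio(t, g, PriorSpec(means_only=True))
        assert np.isfinite(res.log10br)

    def test_deterministic_in_inputs(self, rng):
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=80))
        g = rng.integers(0, 3, 80)
        a = bayes_ratio(t, g)
        b = bayes_ratio(t, g)
        assert a.br == b.br


class TestSequentialUpdate:
    def test_neutral_updates_keep_prior(self):
        assert sequential_update([1.0, 1.0]).ppld == pytest.approx(PI)

    def test_cancellation(self):
        res = sequential_update([10.0, 0.1])
        assert res.br == pytest.approx(1.0)
        assert res.ppld == pytest.approx(PI)

    def test_order_invariance(self):
        brs = [2.5, 0.3, 7.0]
        ref = sequential_update(brs).ppld
        for perm in ([7.0, 2.5, 0.3], [0.3, 7.0, 2.5]):
            assert sequential_update(perm).ppld == pytest.approx(ref, rel=1e-12)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            sequential_update([])
        with pytest.raises(ValueError):
            sequential_update([1.0, -2.0])


class TestScan:
    def test_null_scan_keeps_ppld_small(self, rng):
        n = 200
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n))
        gm = rng.binomial(2, 0.5, size=(30, n))
        table = scan(t, gm, config=PPLDConfig(n_points=4096))
        assert (table["ppld"] < 0.10).mean() >= 0.9

    def test_duplicate_snps_identical_and_flags(self, rng):
        n = 120
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n))
        g = rng.binomial(2, 0.3, size=n).astype(float)
        rare = np.zeros(n)
        rare[:2] = 1.0  # MAF below the 3% floor
        mono = np.ones(n)
        gm = np.vstack([g, g, rare, mono])
        table = scan(t, gm, snp_ids=["a", "b", "rare", "mono"])
        assert table.loc[0, "ppld"] == table.loc[1, "ppld"]
        assert table.loc[2, "flag"] == "low_maf" and np.isnan(table.loc[2, "ppld"])
        assert table.loc[3, "flag"] == "monomorphic"

    def test_missing_genotypes_reduce_n_used(self, rng):
        n = 100
        t = (lambda x: (x - x.mean()) / x.std())(rng.normal(size=n))
        g = rng.binomial(2, 0.5, size=n).astype(float)
        g[:10] = np.nan
        table = scan(t, g[None, :])
        assert table.loc[0, "n_used"] == 90
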