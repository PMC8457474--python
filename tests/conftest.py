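import numpy as np
import pytest

from teppld.simulator import get_model, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20210922)


@pytest.fixture
def null_cohort():
    """A Model-1 (no association) cohort of 400 individuals."""
    return simulate_cohort(get_model("M1"), 400, seed=101)


@pytest.fixture
def additive_cohort():
    """A Model-2 (additive association) cohort of 400 individuals."""
    return simulate_cohort(get_model("M2"), 400, seed=202)


def mc_prior_average_lr(t, g, freqs, n_mc=200_000, seed=5150,
                        mean_bounds=(-3.0, 3.0), sd_bounds=(0.3, 3.0)):
    """Brute-force Monte Carlo prior average of the association LR.

    Independent oracle for the Bayes ratio: uniform draws over the prior box
    and direct normal-density arithmetic, sharing no code with the package's
    integrator. Returns (estimate, standard error).
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    mus = rng.uniform(*mean_bounds, size=(n_mc, 3))
    sds = rng.uniform(*sd_bounds, size=(n_mc, 3))
    loglr = np.zeros(n_mc)
    for ti, gi in zip(t, g):
        num = norm.logpdf(ti, mus[:, gi], sds[:, gi])
        den = np.log(sum(freqs[k] * norm.pdf(ti, mus[:, k], sds[:, k]) for k in range(3)))
        loglr += num - den
    m = loglr.max()
    lr = np.exp(loglr - m)
    return float(lr.mean() * np.exp(m)), float(lr.std() / np.sqrt(n_mc) * np.exp(m))
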