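"""Synthetic survival-GWAS cohorts.

Generates the study conditions used throughout the package: HWE genotypes at a
given minor allele frequency, a binary covariate (e.g. steroid exposure), event
ages drawn from genotype x covariate cells of a generating model, and censoring
by an independent negative-binomial age-at-observation.

Generating models are specified on a standard-normal scale and mapped to years
through the anchor ``t = 11.6 + 3.4 z`` (the mean/SD of age at loss of
ambulation among untreated uncensored individuals in the motivating DMD data),
with +3 years added to the second covariate level unless the model carries
explicit covariate-specific cells. Besides the native truncated mixture-of-
normals family, each cell can be generated from a Weibull, Birnbaum-Saunders or
Gamma distribution moment-matched to the same (untruncated) years-scale mean
and SD, to probe robustness to the shape of the survival distribution.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ANCHOR_MEAN_YEARS",
    "ANCHOR_SD_YEARS",
    "COVARIATE_OFFSET_YEARS",
    "NB_R",
    "NB_P",
    "FAMILIES",
    "GeneratingModel",
    "Cohort",
    "MODELS",
    "get_model",
    "child_rng",
    "draw_genotypes",
    "draw_covariates",
    "cell_distribution",
    "match_moments",
    "draw_observation_age",
    "simulate_arrays",
    "simulate_cohort",
    "sample_chip_maf",
]

ANCHOR_MEAN_YEARS = 11.6
ANCHOR_SD_YEARS = 3.4
COVARIATE_OFFSET_YEARS = 3.0
# Age-at-observation: failures before the r-th success; mean r(1-p)/p = 15 y.
NB_R = 10
NB_P = 0.4
FAMILIES = ("MoN", "WB", "BS", "GM")

_LOG_2PI = np.log(2.0 * np.pi)


def child_rng(base_seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child stream for replicate ``keys`` of a base seed.

    Each (experiment, replicate) pair gets an independent, reproducible
    generator, so studies can be re-run or parallelized piecewise without
    changing their results.
    """
    return np.random.default_rng(np.random.SeedSequence((int(base_seed),) + tuple(int(k) for k in keys)))


@dataclass(frozen=True)
class GeneratingModel:
    """A genotype x covariate trait-distribution model on the standard scale.

    ``std_means``/``std_sds`` have shape (3 genotypes, 2 covariate levels);
    genotype rows are ordered by minor-allele count 0, 1, 2 and covariate
    columns by level y = 1, 2. ``covariate_offset_years`` is added (in years)
    to every y = 2 cell; models whose y = 2 cells are explicit carry offset 0.
    """

    model_id: str
    std_means: np.ndarray
    std_sds: np.ndarray
    family: str = "MoN"
    maf: float = 0.5
    covariate_offset_years: float = COVARIATE_OFFSET_YEARS
    covariate_law: str = "fixed"  # "fixed" (50/50) or "random" (alpha ~ N(0.7, 0.1))
    inheritance: str = "additive"  # generating mode used for "correct" CPH coding
    anchor_mean_years: float = ANCHOR_MEAN_YEARS
    anchor_sd_years: float = ANCHOR_SD_YEARS

    def __post_init__(self):
        m = np.asarray(self.std_means, dtype=float).reshape(3, 2)
        s = np.asarray(self.std_sds, dtype=float).reshape(3, 2)
        object.__setattr__(self, "std_means", m)
        object.__setattr__(self, "std_sds", s)
        if not np.all(s > 0):
            raise ValueError("all std_sds must be > 0")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.covariate_law not in ("fixed", "random"):
            raise ValueError(f"unknown covariate_law {self.covariate_law!r}")

    def replace(self, **kwargs) -> "GeneratingModel":
        return dataclasses.replace(self, **kwargs)

    def cell_mean_sd_years(self, genotype: int, covariate: int) -> tuple[float, float]:
        """Years-scale (untruncated) mean and SD of one genotype x covariate cell."""
        if genotype not in (0, 1, 2) or covariate not in (1, 2):
            raise ValueError("genotype must be 0/1/2 and covariate 1/2")
        mu = self.anchor_mean_years + self.anchor_sd_years * self.std_means[genotype, covariate - 1]
        if covariate == 2:
            mu += self.covariate_offset_years
        sd = self.anchor_sd_years * self.std_sds[genotype, covariate - 1]
        return float(mu), float(sd)


def _baseline(model_id, means, sds, inheritance):
    """Models 1-7 layout: identical std cells for both covariate levels, +3y offset."""
    means = np.repeat(np.asarray(means, float)[:, None], 2, axis=1)
    sds = np.repeat(np.asarray(sds, float)[:, None], 2, axis=1)
    return GeneratingModel(model_id, means, sds, inheritance=inheritance)


def _epi(model_id, means1, sds1, means2, sds2, inheritance):
    """Epistasis layout: explicit y=1/y=2 std cells, +3y offset, random covariate law."""
    means = np.column_stack([means1, means2])
    sds = np.column_stack([sds1, sds2])
    return GeneratingModel(model_id, means, sds, covariate_law="random", inheritance=inheritance)


MODELS: dict[str, GeneratingModel] = {
    "M1": _baseline("M1", [0, 0, 0], [1, 1, 1], "additive"),
    "M2": _baseline("M2", [-0.5, 0, 0.5], [1, 1, 1], "additive"),
    "M3": _baseline("M3", [-0.5, 0, 0.5], [1.25, 1.25, 1.25], "additive"),
    "M4": _baseline("M4", [-0.5, 0.5, 0.5], [1.25, 1.25, 1.25], "dominant"),
    "M5": _baseline("M5", [-0.5, -0.5, 0.5], [1.25, 1.25, 1.25], "recessive"),
    "M6": _baseline("M6", [-0.5, 0, 0.5], [0.5, 1, 1.5], "additive"),
    "M7": _baseline("M7", [0, 0, 0], [0.5, 1, 1.5], "additive"),
    # Model 8: the covariate affects the three genotype cells differently
    # (explicit y=2 means/SDs, no additional +3y shift).
    "M8": GeneratingModel(
        "M8",
        np.array([[-0.5, 1.26], [0.0, 1.76], [0.5, 2.26]]),
        np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]),
        covariate_offset_years=0.0,
        inheritance="additive",
    ),
    # Covariate x genotype interaction (classical epistasis) models: the
    # genotypic effect is present only, or differently, in the y=2 stratum.
    "Epi1": _epi("Epi1", [0, 0, 0], [1, 1, 1], [-0.5, 0.0, 0.5], [1, 1, 1], "additive"),
    "Epi2": _epi("Epi2", [0, 0, 0], [1, 1, 1], [-0.5, 0.5, 0.5], [1, 1, 1], "dominant"),
    "Epi3": _epi("Epi3", [0, 0, 0], [1, 1, 1], [-0.5, -0.5, 0.5], [1, 1, 1], "recessive"),
    "Epi4": _epi("Epi4", [0, 0, 0], [1, 1, 1], [0, 0, 0], [2, 1, 1], "additive"),
    "Epi5": _epi("Epi5", [-0.5, 0, 0], [1, 1, 1], [-0.75, 0, 0], [1, 1, 1], "dominant"),
    "Epi6": _epi("Epi6", [-0.5, 0, 0], [1, 1, 1], [-0.5, 0, 0], [1.5, 1, 1], "dominant"),
    "Epi7": _epi("Epi7", [-0.5, 0, 0], [1, 1, 1], [-0.75, 0, 0], [1.5, 1, 1], "dominant"),
}


def get_model(model_id: str, family: str = "MoN", maf: float = 0.5,
              covariate_law: str | None = None) -> GeneratingModel:
    """Look up a registered generating model, optionally overriding family/MAF/law."""
    try:
        model = MODELS[model_id]
    except KeyError:
        raise KeyError(f"unknown model {model_id!r}; known: {sorted(MODELS)}") from None
    kwargs = {}
    if family != model.family:
        kwargs["family"] = family
    if maf != model.maf:
        kwargs["maf"] = maf
    if covariate_law is not None and covariate_law != model.covariate_law:
        kwargs["covariate_law"] = covariate_law
    return model.replace(**kwargs) if kwargs else model


@dataclass
class Cohort:
    """One row per individual: genotype, covariate level, observed age, event flag."""

    sample_id: np.ndarray
    genotype: np.ndarray
    covariate: np.ndarray
    time: np.ndarray
    event: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id)
        self.genotype = np.asarray(self.genotype, dtype=np.int64)
        self.covariate = np.asarray(self.covariate, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int64)
        n = len(self.sample_id)
        if n == 0:
            raise ValueError("cohort must be nonempty")
        for name in ("genotype", "covariate", "time", "event"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if len(np.unique(self.sample_id)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(self.time > 0):
            raise ValueError("all times must be > 0")
        if not np.all(np.isin(self.genotype, (0, 1, 2))):
            raise ValueError("genotypes must be in {0, 1, 2}")
        if not np.all(np.isin(self.covariate, (1, 2))):
            raise ValueError("covariate must be in {1, 2}")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event must be in {0, 1}")

    def __len__(self) -> int:
        return len(self.sample_id)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "genotype": self.genotype,
                "covariate": self.covariate,
                "time": self.time,
                "event": self.event,
            }
        )

    @classmethod
    def from_frame(cls, df, provenance: str = "") -> "Cohort":
        return cls(
            sample_id=df["sample_id"].to_numpy(),
            genotype=df["genotype"].to_numpy(),
            covariate=df["covariate"].to_numpy(),
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            provenance=provenance,
        )

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            self.sample_id[mask],
            self.genotype[mask],
            self.covariate[mask],
            self.time[mask],
            self.event[mask],
            provenance=self.provenance,
        )


def draw_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Minor-allele counts for ``n`` unrelated individuals under HWE."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    u = rng.random(n)
    return np.searchsorted(np.cumsum(p[:2]), u).astype(np.int64)


def draw_covariates(
    n: int,
    law: str,
    rng: np.random.Generator,
    alpha_mean: float = 0.7,
    alpha_sd: float = 0.1,
) -> np.ndarray:
    """Covariate levels in {1, 2}.

    ``fixed``: the first floor(n/2) individuals get y=1, the rest y=2.
    ``random``: a per-replicate proportion alpha ~ N(alpha_mean, alpha_sd)
    truncated to (0, 1) is drawn once, then each individual is independently
    y=2 with probability alpha.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if law == "fixed":
        y = np.full(n, 2, dtype=np.int64)
        y[: n // 2] = 1
        return y
    if law == "random":
        alpha = rng.normal(alpha_mean, alpha_sd)
        while not (0.0 < alpha < 1.0):
            alpha = rng.normal(alpha_mean, alpha_sd)
        return np.where(rng.random(n) < alpha, 2, 1).astype(np.int64)
    raise ValueError(f"unknown covariate law {law!r}")


@dataclass(frozen=True)
class MomentMatch:
    """Moment-matched parameters of a 2-parameter survival family."""

    family: str
    params: dict
    dist: object  # frozen scipy distribution


def match_moments(family: str, mean: float, sd: float, rtol: float = 1e-6) -> MomentMatch:
    """Parameters of ``family`` whose (mean, SD) equal the given values.

    Gamma has the closed form shape=(mean/sd)^2, scale=sd^2/mean. The
    Birnbaum-Saunders shape solves a quadratic in c^2; the Weibull shape
    solves the coefficient-of-variation equation numerically. Every result
    is round-trip checked to ``rtol`` relative error.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    if family == "GM":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        dist = stats.gamma(shape, scale=scale)
        params = {"shape": shape, "scale": scale}
    elif family == "WB":
        cv2 = (sd / mean) ** 2

        def f(log_k):
            k = np.exp(log_k)
            g1 = special.gammaln(1 + 1 / k)
            g2 = special.gammaln(1 + 2 / k)
            return np.expm1(g2 - 2 * g1) - cv2

        try:
            log_k = optimize.brentq(f, np.log(0.05), np.log(500.0), xtol=1e-13, rtol=8.9e-16)
        except ValueError as exc:
            raise RuntimeError(f"Weibull moment match failed for mean={mean}, sd={sd}") from exc
        k = float(np.exp(log_k))
        lam = mean / special.gamma(1 + 1 / k)
        dist = stats.weibull_min(k, scale=lam)
        params = {"shape": k, "scale": lam}
    elif family == "BS":
        v, m2 = sd**2, mean**2
        # mean = b(1 + a/2), var = b^2 a (1 + 5a/4) with a = c^2:
        # a^2 (v - 5 m^2)/4 + a (v - m^2) + v = 0
        qa, qb, qc = (v - 5 * m2) / 4.0, v - m2, v
        disc = qb**2 - 4 * qa * qc
        if disc < 0:
            raise RuntimeError(f"Birnbaum-Saunders moment match failed for mean={mean}, sd={sd}")
        roots = [(-qb + np.sqrt(disc)) / (2 * qa), (-qb - np.sqrt(disc)) / (2 * qa)]
        pos = [a for a in roots if a > 0]
        if not pos:
            raise RuntimeError(f"Birnbaum-Saunders moment match failed for mean={mean}, sd={sd}")
        a = min(pos)
        c = float(np.sqrt(a))
        b = mean / (1 + a / 2)
        dist = stats.fatiguelife(c, scale=b)
        params = {"shape": c, "scale": b}
    elif family == "MoN":
        raise ValueError("MoN cells are parameterized directly, not moment-matched")
    else:
        raise ValueError(f"unknown family {family!r}")

    got_mean, got_var = dist.stats(moments="mv")
    if abs(got_mean - mean) > rtol * mean or abs(np.sqrt(got_var) - sd) > rtol * sd:
        raise RuntimeError(
            f"moment match for {family} did not converge: target ({mean}, {sd}), "
            f"got ({float(got_mean)}, {float(np.sqrt(got_var))})"
        )
    return MomentMatch(family, params, dist)


@functools.lru_cache(maxsize=512)
def _match_moments_cached(family: str, mean: float, sd: float) -> MomentMatch:
    return match_moments(family, mean, sd)


def cell_distribution(model: GeneratingModel, genotype: int, covariate: int):
    """Frozen event-age distribution (years) of one genotype x covariate cell.

    MoN cells are normal left-truncated at 0; WB/BS/GM cells are the
    2-parameter member of the family matching the untruncated normal moments.
    """
    mean, sd = model.cell_mean_sd_years(genotype, covariate)
    if model.family == "MoN":
        a = (0.0 - mean) / sd
        return stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return _match_moments_cached(model.family, mean, sd).dist


def _sample_cell(model: GeneratingModel, genotype: int, covariate: int,
                 size: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling from one cell (cheap closed forms, reproducible)."""
    mean, sd = model.cell_mean_sd_years(genotype, covariate)
    u = rng.random(size)
    if model.family == "MoN":
        # renormalized truncated normal via the probit
        phi0 = special.ndtr((0.0 - mean) / sd)
        return mean + sd * special.ndtri(phi0 + u * (1.0 - phi0))
    mm = _match_moments_cached(model.family, mean, sd)
    if model.family == "WB":
        k, lam = mm.params["shape"], mm.params["scale"]
        return lam * (-np.log1p(-u)) ** (1.0 / k)
    if model.family == "GM":
        return mm.dist.ppf(u)
    # BS: X = b (cZ/2 + sqrt((cZ/2)^2 + 1))^2 with Z standard normal
    c, b = mm.params["shape"], mm.params["scale"]
    z = special.ndtri(u)
    h = c * z / 2.0
    return b * (h + np.sqrt(h * h + 1.0)) ** 2


def draw_observation_age(
    n: int, rng: np.random.Generator, r: int = NB_R, p: float = NB_P
) -> np.ndarray:
    """Ages at observation: negative binomial (failures before r-th success).

    Mean r(1-p)/p = 15 years at the defaults. Zero draws are redrawn so that
    observation age is strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = rng.negative_binomial(r, p, size=n).astype(float)
    zero = draws == 0
    while np.any(zero):
        draws[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
        zero = draws == 0
    return draws


def simulate_arrays(
    model: GeneratingModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Array-level cohort draw: (genotype, covariate, time, event).

    The lean core of :func:`simulate_cohort`, used directly by the replicate
    studies where constructing labelled cohorts would dominate the runtime.
    """
    g = draw_genotypes(n, model.maf, rng)
    y = draw_covariates(n, model.covariate_law, rng)
    t_event = np.empty(n, dtype=float)
    for gg in (0, 1, 2):
        for yy in (1, 2):
            mask = (g == gg) & (y == yy)
            cnt = int(mask.sum())
            if cnt:
                t_event[mask] = _sample_cell(model, gg, yy, cnt, rng)
    t_event = np.maximum(t_event, 1e-9)  # truncation guard for non-MoN families
    t_obs = draw_observation_age(n, rng)
    event = (t_event < t_obs).astype(np.int64)
    time = np.where(event == 1, t_event, t_obs)
    return g, y, time, event


def simulate_cohort(
    model: GeneratingModel,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate a cohort: genotypes, covariates, event ages, and censoring.

    Each individual's event age t_e comes from their genotype x covariate
    cell; an independent observation age t_o comes from the censoring law.
    If t_e < t_o the event is observed at t_e, otherwise the individual is
    censored at t_o. Deterministic given (model, n, seed).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    g, y, time, event = simulate_arrays(model, n, rng)
    width = max(4, len(str(n)))
    ids = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])
    prov = f"model={model.model_id} family={model.family} maf={model.maf} seed={seed}"
    return Cohort(ids, g, y, time, event, provenance=prov)


def sample_chip_maf(
    n_snps: int,
    rng: np.random.Generator,
    mean: float = 0.23,
    sd: float = 0.14,
    low: float = 0.03,
    high: float = 0.5,
) -> np.ndarray:
    """MAFs mimicking a genotyping array spectrum after a 3% MAF filter.

    A Beta distribution rescaled to (low, high), with parameters solved so
    the rescaled mean and SD match the requested values.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    span = high - low
    m = (mean - low) / span
    s = sd / span
    nu = m * (1 - m) / s**2 - 1.0
    if nu <= 0:
        raise ValueError("requested mean/sd are not attainable by a Beta distribution")
    a, b = m * nu, (1 - m) * nu
    return low + span * rng.beta(a, b, size=n_snps)
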