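# Methods

This note documents the statistical models implemented in `teppld`, the
numerical choices behind them, and what the synthetic-data studies do and do
not establish.

## The TE-PPLD

For a biallelic SNP with genotypes g ∈ {0, 1, 2} (minor-allele counts) and a
standardized quantitative trait t, the trait model is a mixture of three
normals, one per genotype, with parameters
γ = (μ₀, μ₁, μ₂, σ₀, σ₁, σ₂). The likelihood ratio of "trait–marker
association" against "no association" is

    log LR(γ) = Σᵢ [ log φ(tᵢ; μ_{gᵢ}, σ_{gᵢ}) − log Σ_g P(g) φ(tᵢ; μ_g, σ_g) ],

with P(g) the Hardy–Weinberg genotype frequencies at the sample-estimated
allele frequency. This is the reduced form of the general trait–marker LD
likelihood at the fixed operating point θ = 0 (recombination), D′ = 1
(complete standardized LD), admixture = 1, and trait-locus allele frequency
equal to the SNP's: together these identify the trait-locus genotype with the
observed SNP genotype, so the general likelihood is implemented only in this
reduced form. The genotype-specific parameterization spans recessive,
additive and dominant configurations — and effects on variances — without a
user-chosen mode of inheritance.

The Bayes ratio is the prior average BR = ∫ LR(γ) f(γ) dγ, integrated as a
unit (a single prior average of the ratio, not a ratio of two marginal
likelihoods), and the PPLD rescales it to a posterior probability:

    PPLD = π·BR / (π·BR + 1 − π),    π = 0.0004.

PPLD > π is evidence for association and PPLD < π evidence against; under no
association the PPLD distribution concentrates below π as n grows, unlike a
p-value's size-invariant null. Evidence accumulates across independent
cohorts by multiplying BRs before the PPLD transform (sequential updating).

**Prior.** f(γ) is uniform and independent over a box: means on [−3, 3]³ and
SDs on [0.3, 3]³, on the scale of standardized residuals, with no ordering
constraint among genotypic means or SDs. A `means_only` mode collapses the
three SDs to one shared value (a 4-D integral), for isolating mean effects or
checking whether variance effects drive a signal. The prior is the one
genuinely open design choice in the statistic: published TE-PPLD operating
characteristics were produced by software whose exact prior ranges are not
public, so quantities that depend on the absolute size of BR (mean PPLDs,
power at a PPLD threshold) reproduce here to within a few percent rather than
exactly. In our studies the visible effect is a Model-7-style variance-only
power of ≈94% where ≈98% has been reported; all qualitative contrasts (null
shrinkage with n, robustness across generating families, epistasis
stratification, low-MAF stability) are prior-insensitive and reproduce
directly.

**Integration.** The integrand LR(γ) has two structural features that defeat
fixed tensor grids at n ≈ 400: it concentrates at scale ~1/√n around the
per-genotype sample moments, and it equals 1 identically on the 2-D diagonal
{μ₀=μ₁=μ₂, σ₀=σ₁=σ₂}, whose neighbourhood carries most of the null-case
mass. The default scheme is a defensive importance-sampling quadrature with a
three-component proposal:

1. the uniform prior itself (weight 0.25) — bounds every importance weight by
   1/0.25 and guards regions the adapted components miss;
2. a *peak* component (0.40): independent normals centred at the per-genotype
   sample means and SDs with scale 3× their standard errors (pooled-moment
   fallbacks for genotype classes with <2 or <3 members);
3. a *ridge* component (0.35): a common location m ~ N(0, 1.5²) and scale
   s ~ N(1.2, 0.9²) spanning the diagonal, plus per-genotype transverse
   jitter at the peak scales — a closed-form 6-D Gaussian whose density is
   evaluated exactly.

8,192 points are drawn from a fixed internal substream (seeded by a constant,
so `bayes_ratio` is a deterministic function of its inputs and identical SNPs
give identical results), log-sum-exp is used throughout, points outside the
prior box contribute zero, and the result carries a relative Monte-Carlo
standard error and effective sample size in its diagnostics; results whose
relative SE exceeds the configured tolerance (default 0.10) are flagged, not
silently accepted. A tensor Gauss–Legendre grid (`method="grid"`) is kept for
low-dimensional cross-checks; the test suite validates the default scheme
against an independent brute-force uniform Monte-Carlo prior average on small
instances and against the grid on the reduced (fixed-SD) model.

Monomorphic SNPs carry no association information: LR ≡ 1, so BR = 1 and
PPLD = π exactly, rather than an error (by contrast, a regression fit on a
constant predictor is undefined).

## OTE residuals

Covariates enter by preprocessing the phenotype once, independently of
genotype. Within each covariate stratum y a 2-parameter Weibull is fit to
(time, event) by censored-data maximum likelihood: the scale has the closed
form λᵏ = Σ tᵢᵏ / d (d = events) for fixed shape k, so the fit is a bracketed
1-D search on the profile likelihood in log k — robust for small strata. The
ordinary time-to-event residual is

    rᵢ = tᵢ − μ̂_y                    (event observed)
    rᵢ = E[T | T > tᵢ; fit_y] − μ̂_y   (censored),

with μ̂_y = λ̂ Γ(1 + 1/k̂) the fitted stratum mean and the conditional mean
computed through the regularized upper incomplete gamma function (saturating
at tᵢ when survival underflows). Unlike martingale or deviance residuals,
these keep the years scale and the interpretation of an ordinary regression
residual, which is what the trait model above assumes. Residuals are pooled
across strata and standardized to mean 0, SD 1 before PPLD analysis, so the
prior box is scale-free. Under the fitted distribution E[r] = 0 exactly (a
tower-property identity); fitting a Weibull to truncated-normal ages leaves a
small misspecification offset (~0.01 years against a 3.4-year phenotype SD),
which standardization removes. Strata need ≥2 events; single-covariate-level
subsets (as in the epistasis analyses) use one pooled fit.

## Cox proportional-hazards comparator

Per SNP, a Cox regression of (time, event) on the coded genotype (additive
g, recessive 1{g=2}, dominant 1{g≥1}) plus the binary covariate, optionally
their interaction; reported as P = −log₁₀ of the genotype coefficient's Wald
p (computed via the normal log-survival function, stable far into the tail).
Single-cohort fits use lifelines. The replicate studies use a vectorized
Newton solver of the same partial likelihood (descending-time ordering with
censored-before-event tie placement, cumulative risk sums, step-halving,
20-iteration cap mirroring standard survival software; event times are
continuous in all generating models so Efron/Breslow tie corrections are
moot). The batch solver is cross-checked against lifelines to ~1e-4 in the
test suite; the 20-iteration cap means quasi-separated low-MAF recessive fits
return the capped iterate, which is precisely the regime that inflates the
recessive null at MAF 0.1. Constant coded predictors (e.g. no minor-allele
homozygotes under recessive coding) are flagged degenerate, mirroring the NaN
of standard software, as is non-convergence of the single-cohort path.

## Synthetic cohorts

Generating models are specified on a standard-normal scale per genotype ×
covariate cell and mapped to years by t = 11.6 + 3.4·z, the mean/SD of age at
loss of ambulation among untreated uncensored individuals in the motivating
Duchenne muscular dystrophy cohort; covariate level y = 2 (steroid exposure)
adds 3 years except in models whose y = 2 cells are explicit. Event-age
normals are left-truncated at 0 (a >3σ event at the anchor, so untruncated
moments are used everywhere parameters are matched) and sampled by inverse
CDF on the renormalized distribution, for reproducibility. The registered
models are: the null model; additive, dominant, recessive, variance-widened,
mean-and-variance, variance-only, and covariate-complicated alternatives; and
seven covariate×genotype interaction (classical epistasis) models in which
the genotypic effect is absent or different in one covariate stratum.

- **Genotypes:** HWE at a given MAF (default 0.5), unrelated individuals.
- **Covariates:** either an exact 50/50 split, or a per-replicate proportion
  α ~ N(0.7, 0.1) truncated to (0,1) with independent per-individual
  assignment (the epistasis/replication setting).
- **Censoring:** age at observation ~ negative binomial with r = 10, p = 0.4
  in the failures-before-r-th-success parameterization (mean 15 y, variance
  37.5), zeros redrawn. Against the ≈13.1-year mean event age this yields a
  41.9% censoring rate (exact value under the generating laws; reported
  rounded as ≈40%). This parameterization is the only common one consistent
  with that rate and is validated by the calibration tests.
- **Robustness families:** each cell can be generated from a Weibull,
  Birnbaum–Saunders or Gamma distribution matched to the cell's untruncated
  normal mean/SD — Gamma in closed form, Birnbaum–Saunders by a quadratic in
  the squared shape, Weibull by solving the CV equation; all round-trip
  checked to 1e-6 relative error.
- **Chip MAF spectrum:** a Beta rescaled to (0.03, 0.5) with parameters
  solved for mean 0.23, SD 0.14, mimicking a filtered genotyping array
  spectrum (the full array spectrum is not public).

Every replicate r of a study draws from a child stream derived from
(base_seed, r), so studies are bit-reproducible and parallelizable, and any
single replicate can be regenerated in isolation.

**What the simulations do not emulate:** linkage disequilibrium between SNPs
(all SNPs independent), related individuals, population stratification,
HWE violations, genotyping error or missingness, informative censoring, and
covariate misclassification. Passing tests therefore establish the
statistics' operating characteristics under clean, independent-SNP survival
cohorts — not robustness to those real-data complications.

## Study problem sizes

Replicate studies default to sizes that hold Monte-Carlo error well inside
the contrasts of interest: 1,000 replicates for Cox-only quantities
(mean-P SE ≈ 0.08, power SE ≈ 1.1pp), 300 replicates for studies running the
full TE-PPLD integration per replicate (power SE ≈ 1.4pp), 10⁶ genotype-only
replicates for degeneracy counting, and 10⁵ replicates for the recessive
null-tail rate (SE ≈ 10% of the rate). All are configurable. Power estimates
always carry binomial standard errors; comparisons against external values
are made in ±3-SE bands combining both sides' Monte-Carlo error.

## Degenerate inputs and tie-breaks

- Monomorphic SNP → BR = 1; MAF below the scan floor (default 3%) → flagged,
  skipped; per-SNP errors flag the row without stopping a scan.
- Missing genotypes → per-SNP complete-case analysis with n_used reported.
- `threshold_top_k` returns the k-th largest value; tied boundary values all
  sit at-or-above the threshold.
- Weibull fits require ≥2 events; callers may fall back to pooled strata.
- Empirical-threshold studies resolve ties by sorted position.

## Known limitations

- Absolute BR magnitudes (hence mean PPLDs and PPLD-threshold power) are
  prior-dependent; see the Prior section. Rank orderings and evidence
  directions are much less sensitive.
- The importance-sampling integrator is deterministic given its inputs but
  carries Monte-Carlo error (reported per result); at default settings the
  relative SE on BR is typically 3–15% at n = 400, far inside the
  replicate-to-replicate spread of the statistic itself.
- Related individuals (pedigree likelihoods) are out of scope; cohorts are
  assumed unrelated.
- The Cox comparator's covariate is a single binary indicator; stratified and
  frailty models, time-varying effects, and Firth-type corrections are not
  implemented.
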