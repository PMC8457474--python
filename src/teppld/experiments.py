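"""Simulation-evaluation studies.

Drivers that reproduce, at configurable (typically desk-scale) replicate
counts, the evaluation experiments for the TE-PPLD and its Cox
proportional-hazards comparator: null calibration and empirical thresholds,
power and robustness across generating families, low-MAF behavior, covariate
x genotype (epistasis) stratification, independent replication versus
Bayesian sequential updating, and a genome-scan mimic with follow-up in a
replication set.

Every study derives one child random stream per replicate from
``(base_seed, replicate)``, so results are bit-reproducible and individual
replicates can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cph as cph_mod
from .cph import cox_scan_batch
from .ppld import PI, BRResult, PPLDConfig, PriorSpec, bayes_ratio, ppld_from_br, sequential_update
from .residuals import FitError, ote_residuals, standardize
from .simulator import (
    MODELS,
    Cohort,
    GeneratingModel,
    child_rng,
    get_model,
    sample_chip_maf,
    simulate_arrays,
    simulate_cohort,
)

__all__ = [
    "ExperimentConfig",
    "NullCalibration",
    "threshold_top_k",
    "simulate_batch",
    "te_ppld_for_cohort",
    "te_ppld_batch",
    "null_study",
    "power_study",
    "epistasis_study",
    "replication_study",
    "genome_scan_experiment",
]


@dataclass
class ExperimentConfig:
    """Shared knobs for the replicate studies."""

    base_seed: int = 0
    n_reps: int = 200
    sample_sizes: tuple = (400,)
    models: tuple = ("M1",)
    statistics: tuple = ("CPH-P",)  # subset of {"CPH-P", "TE-PPLD"}
    thresholds: dict = field(default_factory=lambda: {"CPH-P": 5.0, "TE-PPLD": 0.0201})
    top_k: int = 32
    cph_mode: str | None = None  # None: the generating mode of inheritance
    prior: PriorSpec = field(default_factory=PriorSpec)
    ppld_config: PPLDConfig = field(default_factory=PPLDConfig)

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for stat, thr in self.thresholds.items():
            if thr <= 0:
                raise ValueError(f"threshold for {stat} must be positive")

    def resolve_models(self) -> list[GeneratingModel]:
        out = []
        for m in self.models:
            out.append(get_model(m) if isinstance(m, str) else m)
        return out


@dataclass
class NullCalibration:
    """Per-replicate null statistics and the empirical top-k threshold."""

    condition: str
    statistic: str
    values: np.ndarray
    top_k: int
    threshold: float
    frac_above_pi: float = np.nan  # TE-PPLD only


def threshold_top_k(values, k: int) -> float:
    """The k-th largest value: the empirical threshold demarcating the top k."""
    v = np.asarray(values, dtype=float)
    if not (1 <= k <= v.size):
        raise ValueError(f"k must be in [1, {v.size}], got {k}")
    return float(np.partition(v, v.size - k)[v.size - k])


def simulate_batch(
    model: GeneratingModel, n: int, n_reps: int, base_seed: int
) -> dict[str, np.ndarray]:
    """Stacked (n_reps, n) arrays of replicate cohorts (one child stream each)."""
    g = np.empty((n_reps, n), dtype=np.int64)
    y = np.empty((n_reps, n), dtype=np.int64)
    t = np.empty((n_reps, n), dtype=float)
    e = np.empty((n_reps, n), dtype=np.int64)
    for r in range(n_reps):
        g[r], y[r], t[r], e[r] = simulate_arrays(model, n, child_rng(base_seed, r))
    return {"genotype": g, "covariate": y, "time": t, "event": e}


def te_ppld_for_cohort(
    cohort: Cohort,
    prior: PriorSpec | None = None,
    config: PPLDConfig | None = None,
    stratify: bool = True,
) -> BRResult:
    """Full TE-PPLD pipeline for one cohort: residuals, standardize, BR."""
    res = standardize(ote_residuals(cohort, stratify_on_covariate=stratify))
    return bayes_ratio(res.values, cohort.genotype, prior, config)


def te_ppld_batch(
    model: GeneratingModel,
    n: int,
    n_reps: int,
    base_seed: int,
    prior: PriorSpec | None = None,
    config: PPLDConfig | None = None,
) -> pd.DataFrame:
    """TE-PPLD per replicate cohort; failed residual fits are flagged rows."""
    rows = []
    for r in range(n_reps):
        cohort = simulate_cohort(model, n, rng=child_rng(base_seed, r))
        try:
            res = te_ppld_for_cohort(cohort, prior, config)
            rows.append((r, res.log10br, res.ppld, res.br, ""))
        except FitError as exc:
            rows.append((r, np.nan, np.nan, np.nan, str(exc)))
    return pd.DataFrame(rows, columns=["rep", "log10br", "ppld", "br", "flag"])


def _cph_batch_P(model, n, n_reps, base_seed, mode) -> np.ndarray:
    batch = simulate_batch(model, n, n_reps, base_seed)
    out = cox_scan_batch(batch["time"], batch["event"], batch["genotype"], batch["covariate"], mode)
    return out["P"].to_numpy()


def null_study(config: ExperimentConfig) -> list[NullCalibration]:
    """Null sampling distributions and empirical thresholds per condition.

    Each configured model (a null generating condition, typically the
    no-association model under a family/MAF variant) and sample size yields
    per-replicate CPH-P and/or TE-PPLD values, the top-k threshold, and for
    the TE-PPLD the fraction of replicates with PPLD > pi.
    """
    out: list[NullCalibration] = []
    mode = config.cph_mode or "additive"
    for mi, model in enumerate(config.resolve_models()):
        for ni, n in enumerate(config.sample_sizes):
            label = f"{model.model_id}/{model.family}/maf={model.maf}/N={n}"
            seed_key = (config.base_seed, 1000 * mi + ni)
            if "CPH-P" in config.statistics:
                P = _cph_batch_P(model, n, config.n_reps, hash_seed(*seed_key), mode)
                vals = P[~np.isnan(P)]
                k = min(config.top_k, vals.size)
                out.append(NullCalibration(label, "CPH-P", vals, k, threshold_top_k(vals, k)))
            if "TE-PPLD" in config.statistics:
                df = te_ppld_batch(model, n, config.n_reps, hash_seed(*seed_key),
                                   config.prior, config.ppld_config)
                vals = df["ppld"].dropna().to_numpy()
                k = min(config.top_k, vals.size)
                out.append(
                    NullCalibration(
                        label, "TE-PPLD", vals, k, threshold_top_k(vals, k),
                        frac_above_pi=float(np.mean(vals > config.ppld_config.pi)),
                    )
                )
    return out


def hash_seed(base_seed: int, key: int) -> int:
    """A distinct sub-seed per study condition, kept below 2^31."""
    return int((int(base_seed) * 1_000_003 + int(key)) % 2_147_483_647)


def power_study(config: ExperimentConfig) -> pd.DataFrame:
    """Mean (SD) and empirical power per model x family x statistic.

    Power is the fraction of replicates at or above the statistic's
    threshold; binomial standard errors accompany every power estimate.
    """
    rows = []
    for mi, model in enumerate(config.resolve_models()):
        for ni, n in enumerate(config.sample_sizes):
            seed = hash_seed(config.base_seed, 1000 * mi + ni)
            if "CPH-P" in config.statistics:
                mode = config.cph_mode or model.inheritance
                P = _cph_batch_P(model, n, config.n_reps, seed, mode)
                ok = P[~np.isnan(P)]
                thr = config.thresholds["CPH-P"]
                pw = float(np.mean(ok >= thr))
                rows.append(
                    dict(
                        model=model.model_id, family=model.family, N=n, statistic="CPH-P",
                        mode=mode, n_reps=ok.size, mean=float(np.mean(ok)), sd=float(np.std(ok, ddof=1)),
                        threshold=thr, power=pw, power_se=float(np.sqrt(pw * (1 - pw) / max(ok.size, 1))),
                    )
                )
            if "TE-PPLD" in config.statistics:
                df = te_ppld_batch(model, n, config.n_reps, seed, config.prior, config.ppld_config)
                vals = df["ppld"].dropna().to_numpy()
                thr = config.thresholds["TE-PPLD"]
                pw = float(np.mean(vals >= thr))
                rows.append(
                    dict(
                        model=model.model_id, family=model.family, N=n, statistic="TE-PPLD",
                        mode="-", n_reps=vals.size, mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1)),
                        threshold=thr, power=pw, power_se=float(np.sqrt(pw * (1 - pw) / max(vals.size, 1))),
                    )
                )
    return pd.DataFrame(rows)


def epistasis_study(config: ExperimentConfig) -> pd.DataFrame:
    """Pooled vs covariate-stratified TE-PPLD and CPH with/without interaction.

    Per replicate: TE-PPLD on the pooled cohort (covariate-adjusted
    residuals), TE-PPLD within each covariate stratum (pooled-fit residuals
    inside the subset, since the covariate is constant there), and CPH with
    and without a y x genotype interaction term. An interaction is called
    when TE-PPLD(y=2) exceeds both the pooled TE-PPLD and the configured
    TE-PPLD threshold.
    """
    thr = config.thresholds.get("TE-PPLD", 0.0201)
    rows = []
    for mi, model in enumerate(config.resolve_models()):
        seed = hash_seed(config.base_seed, mi)
        mode = config.cph_mode or model.inheritance
        n = config.sample_sizes[0]
        rec = dict.fromkeys(
            ["ppld_pooled", "ppld_y1", "ppld_y2", "P_geno", "P_geno_gt", "P_inter"], None
        )
        per_rep = {k: [] for k in rec}
        n_flagged = 0
        called = []
        for r in range(config.n_reps):
            cohort = simulate_cohort(model, n, rng=child_rng(seed, r))
            try:
                pooled = te_ppld_for_cohort(cohort, config.prior, config.ppld_config)
                sub = {}
                for y in (1, 2):
                    part = cohort.subset(cohort.covariate == y)
                    resid = standardize(ote_residuals(part, stratify_on_covariate=False))
                    sub[y] = bayes_ratio(resid.values, part.genotype, config.prior, config.ppld_config)
            except FitError:
                n_flagged += 1
                continue
            cox_plain = cph_mod.cph_p(cohort, mode)
            cox_inter = cph_mod.cph_p(cohort, mode, include_interaction=True)
            per_rep["ppld_pooled"].append(pooled.ppld)
            per_rep["ppld_y1"].append(sub[1].ppld)
            per_rep["ppld_y2"].append(sub[2].ppld)
            per_rep["P_geno"].append(cox_plain.P if not cox_plain.degenerate else np.nan)
            per_rep["P_geno_gt"].append(cox_inter.P if not cox_inter.degenerate else np.nan)
            per_rep["P_inter"].append(cox_inter.interaction_P if not cox_inter.degenerate else np.nan)
            called.append(sub[2].ppld > pooled.ppld and sub[2].ppld >= thr)
        row = dict(model=model.model_id, n_reps=len(called), n_flagged=n_flagged)
        for k, v in per_rep.items():
            a = np.asarray(v, dtype=float)
            row[f"{k}_mean"] = float(np.nanmean(a)) if a.size else np.nan
            row[f"{k}_sd"] = float(np.nanstd(a, ddof=1)) if a.size > 1 else np.nan
        row["interaction_call_rate"] = float(np.mean(called)) if called else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_cohort(a: Cohort, b: Cohort) -> Cohort:
    ids = np.concatenate([np.char.add("A_", a.sample_id.astype(str)),
                          np.char.add("B_", b.sample_id.astype(str))])
    return Cohort(
        ids,
        np.concatenate([a.genotype, b.genotype]),
        np.concatenate([a.covariate, b.covariate]),
        np.concatenate([a.time, b.time]),
        np.concatenate([a.event, b.event]),
        provenance="pooled",
    )


def replication_study(
    config: ExperimentConfig,
    init_model: str | GeneratingModel = "Epi1",
    rep_model: str | GeneratingModel = "Epi1",
    null_model: str | GeneratingModel = "M1",
    n_init: int = 400,
    n_rep: int = 200,
    cand_band: tuple = (5.6, 5.8),
    rep_threshold: float = 5.0,
    max_tries: int = 5000,
) -> dict:
    """Independent replication versus sequential updating, per candidate SNP.

    An initial dataset is selected by rejection so its additive CPH-P lands in
    ``cand_band`` (mimicking follow-up of a specific association signal). For
    each of ``config.n_reps`` replication sets (generated under the
    association model and under the null in parallel) the study records:
    Criterion 1 (the replication set alone reaches P >= ``rep_threshold``),
    Criterion 2 (pooled mega-analysis reaches the threshold), whether the
    pooled TE-PPLD exceeds the initial TE-PPLD, and whether the replication
    set's own BR exceeds 1 (sequential-update success).
    """
    init_model = get_model(init_model) if isinstance(init_model, str) else init_model
    rep_model = get_model(rep_model) if isinstance(rep_model, str) else rep_model
    null_model = get_model(null_model) if isinstance(null_model, str) else null_model
    if null_model.covariate_law != rep_model.covariate_law:
        null_model = null_model.replace(covariate_law=rep_model.covariate_law)
    want_te = "TE-PPLD" in config.statistics

    init_cohort = None
    init_P = np.nan
    for tries in range(max_tries):
        cohort = simulate_cohort(init_model, n_init, rng=child_rng(config.base_seed, 900_000 + tries))
        res = cph_mod.cph_p(cohort, "additive")
        if not res.degenerate and cand_band[0] <= res.P <= cand_band[1]:
            init_cohort, init_P = cohort, res.P
            break
    if init_cohort is None:
        raise RuntimeError(f"no candidate dataset with CPH-P in {cand_band} after {max_tries} tries")

    init_te = te_ppld_for_cohort(init_cohort, config.prior, config.ppld_config) if want_te else None

    recs = {"HA": [], "H0": []}
    for label, model, offset in (("HA", rep_model, 0), ("H0", null_model, 500_000)):
        for r in range(config.n_reps):
            rep_cohort = simulate_cohort(model, n_rep, rng=child_rng(config.base_seed, offset + r))
            rep_res = cph_mod.cph_p(rep_cohort, "additive")
            pooled = _pooled_cohort(init_cohort, rep_cohort)
            pooled_res = cph_mod.cph_p(pooled, "additive")
            rec = {
                "criterion1": bool(not rep_res.degenerate and rep_res.P >= rep_threshold),
                "criterion2": bool(not pooled_res.degenerate and pooled_res.P >= rep_threshold),
            }
            if want_te:
                rep_te = te_ppld_for_cohort(rep_cohort, config.prior, config.ppld_config)
                pooled_te = te_ppld_for_cohort(pooled, config.prior, config.ppld_config)
                updated = sequential_update([init_te.br, rep_te.br], config.ppld_config.pi)
                rec.update(
                    pooled_ppld_gt_init=bool(pooled_te.ppld > init_te.ppld),
                    repset_br_gt_1=bool(rep_te.br > 1.0),
                    updated_ppld=updated.ppld,
                )
            recs[label].append(rec)

    out = {
        "cand_cph_P": float(init_P),
        "cand_ppld": float(init_te.ppld) if want_te else np.nan,
        "n_repsets": config.n_reps,
    }
    for label in ("HA", "H0"):
        df = pd.DataFrame(recs[label])
        for col in df.columns:
            if df[col].dtype == bool:
                out[f"{col}_{label}"] = float(df[col].mean())
        out[f"detail_{label}"] = df
    return out


_HA_SCAN_MODELS = ("M2", "M3", "M4", "M5", "M6", "M7", "M8",
                   "Epi1", "Epi2", "Epi3", "Epi4", "Epi5", "Epi6", "Epi7")


def genome_scan_experiment(
    config: ExperimentConfig,
    n_null_snps: int = 1000,
    n_init: int = 400,
    n_rep: int = 200,
    te_thresholds: tuple = (0.0430, 0.10, 0.40),
    cph_thresholds: tuple = (5.0, 7.3),
    rep_threshold: float = 5.0,
) -> dict:
    """A scaled genome-scan mimic with follow-up in a replication set.

    Every SNP is an independent dataset: its MAF is drawn from the chip-MAF
    spectrum, its covariate proportion from N(0.7, 0.1), and its phenotype
    from its own generating model -- the null model for ``n_null_snps`` SNPs
    and one SNP from each of the 14 association models. Initial-scan
    candidates crossing each threshold are followed up in a replication set
    generated from the same model and MAF: replication by the p-value
    criteria for CPH, confirmation by sequential updating (replication-set
    BR > 1) for the TE-PPLD. Counts of true/false positives, replication and
    confirmation, and the rank order of the association SNPs are returned.
    """
    want_te = "TE-PPLD" in config.statistics
    want_cph = "CPH-P" in config.statistics
    rng = child_rng(config.base_seed, 777)
    mafs = sample_chip_maf(n_null_snps + len(_HA_SCAN_MODELS), rng)

    snp_rows = []
    specs = [("null", "M1")] * n_null_snps + [("ha", m) for m in _HA_SCAN_MODELS]
    for j, (kind, model_id) in enumerate(specs):
        model = get_model(model_id, maf=float(np.clip(mafs[j], 0.03, 0.5)), covariate_law="random")
        init = simulate_cohort(model, n_init, rng=child_rng(config.base_seed, 2 * j))
        row = dict(snp=j, kind=kind, model=model_id, maf=model.maf)
        if want_cph:
            res = cph_mod.cph_p(init, "additive")
            row["cph_P"] = res.P if not res.degenerate else np.nan
        if want_te:
            te = te_ppld_for_cohort(init, config.prior, config.ppld_config)
            row["ppld"] = te.ppld
            row["br"] = te.br
        snp_rows.append((row, model))
    initial = pd.DataFrame([r for r, _ in snp_rows])

    tables = []
    is_ha = (initial["kind"] == "ha").to_numpy()

    def followup(j: int) -> Cohort:
        model = snp_rows[j][1]
        return simulate_cohort(model, n_rep, rng=child_rng(config.base_seed, 2 * j + 1))

    if want_cph:
        P = initial["cph_P"].to_numpy()
        for thr in cph_thresholds:
            hit = np.nan_to_num(P, nan=-np.inf) >= thr
            cand = np.flatnonzero(hit)
            n_true_rep = n_false_rep = 0
            for j in cand:
                rep = followup(j)
                rep_res = cph_mod.cph_p(rep, "additive")
                pooled_res = cph_mod.cph_p(_pooled_cohort(simulate_cohort(
                    snp_rows[j][1], n_init, rng=child_rng(config.base_seed, 2 * j)), rep), "additive")
                replicated = (not rep_res.degenerate and rep_res.P >= rep_threshold) or (
                    not pooled_res.degenerate and pooled_res.P >= rep_threshold
                )
                if replicated:
                    if is_ha[j]:
                        n_true_rep += 1
                    else:
                        n_false_rep += 1
            tp, fp = int(np.sum(hit & is_ha)), int(np.sum(hit & ~is_ha))
            tables.append(
                dict(statistic="CPH-P", threshold=thr, n_true_pos=tp, n_false_pos=fp,
                     tpr=tp / max(tp + fp, 1), n_true_rep=n_true_rep, n_false_rep=n_false_rep,
                     trr=n_true_rep / max(n_true_rep + n_false_rep, 1))
            )
    if want_te:
        ppld = initial["ppld"].to_numpy()
        for thr in te_thresholds:
            hit = np.nan_to_num(ppld, nan=-np.inf) >= thr
            cand = np.flatnonzero(hit)
            n_true_conf = n_false_conf = 0
            for j in cand:
                rep = followup(j)
                rep_te = te_ppld_for_cohort(rep, config.prior, config.ppld_config)
                if rep_te.br > 1.0:  # sequential update raises the PPLD
                    if is_ha[j]:
                        n_true_conf += 1
                    else:
                        n_false_conf += 1
            tp, fp = int(np.sum(hit & is_ha)), int(np.sum(hit & ~is_ha))
            tables.append(
                dict(statistic="TE-PPLD", threshold=thr, n_true_pos=tp, n_false_pos=fp,
                     tpr=tp / max(tp + fp, 1), n_true_rep=n_true_conf, n_false_rep=n_false_conf,
                     trr=n_true_conf / max(n_true_conf + n_false_conf, 1))
            )

    ranks = {}
    for col, stat in (("ppld", "TE-PPLD"), ("cph_P", "CPH-P")):
        if col in initial:
            v = np.nan_to_num(initial[col].to_numpy(), nan=-np.inf)
            order = np.argsort(-v, kind="stable")
            rank_of = np.empty_like(order)
            rank_of[order] = np.arange(1, v.size + 1)
            ranks[stat] = {
                initial.loc[j, "model"]: int(rank_of[j]) for j in np.flatnonzero(is_ha)
            }
    return {"initial": initial, "summary": pd.DataFrame(tables), "ranks": ranks}
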