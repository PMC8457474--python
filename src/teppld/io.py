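"""File formats: cohort/results TSV, genotype TSV, VCF (read-only).

Readers validate rather than coerce: malformed rows raise with the offending
row named, and every skipped VCF record is counted. Genotypes are reduced to
minor-allele counts at load time; the association methods are per-SNP and
position-free, so no coordinates or strand information is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import Cohort

logger = logging.getLogger("teppld")

__all__ = [
    "GenotypeMatrix",
    "read_cohort",
    "write_cohort",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_results",
    "format_ppld",
]

_COHORT_COLUMNS = ("sample_id", "covariate", "time", "event")


@dataclass
class GenotypeMatrix:
    """Per-SNP minor-allele counts, sample order aligned to a cohort.

    ``counts`` has shape (n_snps, n_samples) with NaN for missing entries.
    """

    snp_ids: np.ndarray
    counts: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.counts.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_snps, n_samples)")
        finite = self.counts[np.isfinite(self.counts)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValueError("genotype entries must be 0/1/2 or missing")

    @property
    def maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.counts, axis=1) / 2.0
        return np.minimum(f, 1.0 - f)


def write_cohort(cohort: Cohort, path) -> None:
    """Tab-separated cohort table with a ``#`` provenance comment line."""
    with open(path, "w") as fh:
        if cohort.provenance:
            fh.write(f"# {cohort.provenance}\n")
        fh.write("sample_id\tgenotype\tcovariate\ttime\tevent\n")
        for i in range(len(cohort)):
            fh.write(
                f"{cohort.sample_id[i]}\t{cohort.genotype[i]}\t{cohort.covariate[i]}"
                f"\t{cohort.time[i]:.10g}\t{cohort.event[i]}\n"
            )


def read_cohort(path) -> Cohort:
    """Read a cohort TSV (columns sample_id, [genotype,] covariate, time, event)."""
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            provenance = first.lstrip("#").strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing required columns: {missing}")
    if "genotype" not in df.columns:
        df["genotype"] = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.time > 0:
            raise ValueError(f"{path}: non-positive time at line {i}")
        if row.event not in (0, 1):
            raise ValueError(f"{path}: event must be 0/1 at line {i}")
        if row.covariate not in (1, 2):
            raise ValueError(f"{path}: covariate must be 1/2 at line {i}")
        if row.genotype not in (0, 1, 2):
            raise ValueError(f"{path}: genotype must be 0/1/2 at line {i}")
    return Cohort.from_frame(df, provenance=provenance or "real-data")


def read_genotypes_tsv(path, sample_order=None) -> GenotypeMatrix:
    """Wide genotype TSV: first column snp_id, one column per sample, entries 0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = np.asarray(df.columns)
    counts = df.to_numpy(dtype=float)
    gm = GenotypeMatrix(np.asarray(df.index), counts, samples)
    if sample_order is not None:
        gm = _align_samples(gm, np.asarray(sample_order), path)
    return gm


def _align_samples(gm: GenotypeMatrix, sample_order: np.ndarray, path) -> GenotypeMatrix:
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    absent = [s for s in sample_order if s not in pos]
    if absent:
        raise ValueError(f"{path}: samples absent from genotype data: {absent[:10]}")
    idx = np.array([pos[s] for s in sample_order])
    return GenotypeMatrix(gm.snp_ids, gm.counts[:, idx], sample_order)


def read_genotypes_vcf(path, sample_order=None) -> GenotypeMatrix:
    """Biallelic SNP genotypes from a VCF, as minor-allele counts.

    Multi-allelic and non-SNP records are skipped (with a logged count);
    missing GT calls become NaN. The minor allele is defined per SNP from
    the loaded samples, so counts are flipped when the ALT allele is major.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples)
    snp_ids, rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = ALT count, 3 = missing
        alt = np.asarray(var.gt_types, dtype=float)
        alt[alt == 3] = np.nan
        with np.errstate(invalid="ignore"):
            f_alt = np.nanmean(alt) / 2.0
        counts = 2.0 - alt if f_alt > 0.5 else alt
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(counts)
    if n_skipped:
        logger.info("read_genotypes_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records found")
    gm = GenotypeMatrix(np.asarray(snp_ids), np.vstack(rows), samples)
    if sample_order is not None:
        gm = _align_samples(gm, np.asarray(sample_order), path)
    return gm


def format_ppld(value: float) -> str:
    """PPLD display: 4 decimals below 0.01 (to show the side of pi), else 2."""
    if not np.isfinite(value):
        return "NA"
    return f"{value:.4f}" if value < 0.01 else f"{value:.2f}"


def write_results(table: pd.DataFrame, path) -> None:
    """Deterministic TSV output; PPLD columns follow the two-tier decimal rule."""
    df = table.copy()
    for col in df.columns:
        if col == "ppld" or col.startswith("ppld"):
            df[col] = [format_ppld(v) for v in df[col]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
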