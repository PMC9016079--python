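"""Input readers, quality-control filters and summary-statistics tables.

Quality control follows the allele-specific analysis conventions: imputed
genotypes are kept only above a strict imputation-quality threshold
(R^2 > 0.96 by default; directly genotyped calls bypass the filter), imputed
genotypes are cross-checked against the RNA-seq allele counts when coverage
exceeds 20 reads, lowly expressed exonic loci (mean raw count < 2) are
dropped, and candidate genes are those whose TSS lies within +/- 500 kb of
the GWAS SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "GenotypeRecord",
    "AllelicCountRecord",
    "AssociationRecord",
    "ConsistencyStatus",
    "read_phased_vcf",
    "filter_imputation_quality",
    "genotype_consistency_check",
    "filter_low_expression",
    "select_cis_pairs",
    "read_allelic_counts",
    "write_summary_stats",
    "read_summary_stats",
]

CIS_WINDOW = 500_000
SUMMARY_COLUMNS = [
    "gwas_snp",
    "exonic_snp",
    "gene",
    "beta",
    "se",
    "p",
    "fdr_p",
    "n_double_het",
    "r_genotype",
    "r_allelic",
    "category",
]


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int  # 1-based, VCF convention

    def __str__(self):
        return f"{self.chrom}:{self.pos}"


@dataclass
class GenotypeRecord:
    """One subject's genotype at one locus."""

    subject_id: str
    locus: Locus
    allele_pair: tuple[str, str] | None
    phased: bool
    imputation_r2: float | None = None
    genotyped: bool = False  # direct call, not imputed
    missing: bool = False


@dataclass
class AllelicCountRecord:
    """Per-subject allele counts at one exonic locus."""

    subject_id: str
    exonic_locus: Locus
    count_by_allele: dict[str, float]
    library_size: float
    cell_type: str | None = None

    def __post_init__(self):
        if any(c < 0 for c in self.count_by_allele.values()):
            raise ValueError("counts must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.count_by_allele.values()))


@dataclass
class AssociationRecord:
    """One tested (GWAS SNP, exonic SNP, gene) association."""

    gwas_snp: str
    exonic_snp: str
    gene: str
    beta: float
    se: float
    p: float
    fdr_p: float = float("nan")
    n_double_het: int = 0
    r_genotype: float = float("nan")
    r_allelic: float = float("nan")
    category: int | None = None


class ConsistencyStatus(Enum):
    CONSISTENT = "consistent"
    OVERRIDE_TO_RNASEQ_CALL = "override_to_rnaseq_call"
    INSUFFICIENT_DEPTH = "insufficient_depth"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_phased_vcf(path: str, loci_of_interest=None) -> list[GenotypeRecord]:
    """Read per-subject genotypes from a VCF with GT fields.

    ``loci_of_interest`` is an optional collection of (chrom, pos) pairs (or
    ``Locus``); loci absent from the file produce a warning.  The phased
    flag comes from the GT separator and ``imputation_r2`` from the INFO R2
    key when present; records without an R2 are treated as directly
    genotyped.
    """
    wanted = None
    if loci_of_interest is not None:
        wanted = {
            (l.chrom, l.pos) if isinstance(l, Locus) else (str(l[0]), int(l[1]))
            for l in loci_of_interest
        }
    seen = set()
    records: list[GenotypeRecord] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            key = (rec.chrom, rec.pos)
            if wanted is not None and key not in wanted:
                continue
            seen.add(key)
            locus = Locus(rec.chrom, rec.pos)
            alleles = rec.alleles
            r2 = rec.info.get("R2", None)
            if isinstance(r2, tuple):
                r2 = r2[0]
            typed = "TYPED" in rec.info or r2 is None
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or any(g is None for g in gt):
                    records.append(
                        GenotypeRecord(s, locus, None, False, r2, typed, missing=True)
                    )
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"malformed GT for subject {s} at {locus}: {gt}"
                    )
                try:
                    pair = (alleles[gt[0]], alleles[gt[1]])
                except IndexError as exc:
                    raise ValueError(
                        f"malformed GT for subject {s} at {locus}: {gt}"
                    ) from exc
                records.append(
                    GenotypeRecord(s, locus, pair, bool(call.phased), r2, typed)
                )
    if wanted is not None:
        for missing in sorted(wanted - seen):
            logger.warning("locus %s:%s not found in %s", *missing, path)
    return records


def read_allelic_counts(path: str) -> list[AllelicCountRecord]:
    """Read the allelic-count TSV (subject_id, chrom, pos, allele, count,
    library_size [, cell_type])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    has_ct = "cell_type" in df.columns
    keys = ["subject_id", "chrom", "pos"] + (["cell_type"] if has_ct else [])
    out = []
    for key, grp in df.groupby(keys, sort=False):
        key = dict(zip(keys, key))
        out.append(
            AllelicCountRecord(
                subject_id=str(key["subject_id"]),
                exonic_locus=Locus(str(key["chrom"]), int(key["pos"])),
                count_by_allele=dict(zip(grp["allele"], grp["count"].astype(float))),
                library_size=float(grp["library_size"].iloc[0]),
                cell_type=str(key["cell_type"]) if has_ct else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def filter_imputation_quality(
    records: list[GenotypeRecord], r2_min: float = 0.96
) -> list[GenotypeRecord]:
    """Keep imputed genotypes with R^2 strictly above ``r2_min``.

    Directly genotyped records (no imputation score) bypass the filter,
    which exists to control phasing errors of imputed calls.
    """
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must be in [0, 1]")
    kept = [
        r
        for r in records
        if (r.imputation_r2 is not None and r.imputation_r2 > r2_min)
        or (r.imputation_r2 is None and r.genotyped)
    ]
    logger.info(
        "imputation-quality filter: kept %d / %d records", len(kept), len(records)
    )
    return kept


def genotype_consistency_check(
    imputed_het: bool, counts: tuple[float, float], depth_min: int = 20
) -> tuple[ConsistencyStatus, str]:
    """Cross-check an imputed genotype against RNA-seq allele counts.

    The allele-count ratio is min/max.  With more than ``depth_min`` reads,
    a homozygous call with ratio > 10% or a heterozygous call with ratio
    < 2% is overridden by the RNA-seq-implied genotype (het if the ratio is
    at least 2%, otherwise homozygous for the major allele).  Returns the
    status and the resolved call ('het' or 'hom').
    """
    c1, c2 = counts
    if c1 < 0 or c2 < 0:
        raise ValueError("negative allele counts")
    total = c1 + c2
    imputed = "het" if imputed_het else "hom"
    if total <= depth_min:
        return ConsistencyStatus.INSUFFICIENT_DEPTH, imputed
    hi, lo = max(c1, c2), min(c1, c2)
    ratio = lo / hi if hi > 0 else 0.0
    rnaseq_call = "het" if ratio >= 0.02 else "hom"
    if (not imputed_het and ratio > 0.10) or (imputed_het and ratio < 0.02):
        return ConsistencyStatus.OVERRIDE_TO_RNASEQ_CALL, rnaseq_call
    return ConsistencyStatus.CONSISTENT, imputed


def filter_low_expression(
    counts_by_locus: dict, min_mean: float = 2.0
) -> set:
    """Retain loci whose mean total count across subjects is >= ``min_mean``.

    ``counts_by_locus`` maps a locus to the per-subject total counts at that
    locus (one entry per subject in the analysis set).
    """
    retained = set()
    for locus, counts in counts_by_locus.items():
        counts = list(counts)
        if not counts:
            raise ValueError(f"empty subject set for locus {locus}")
        if float(np.mean(counts)) >= min_mean:
            retained.add(locus)
    logger.info(
        "low-expression filter: retained %d / %d loci",
        len(retained),
        len(counts_by_locus),
    )
    return retained


def select_cis_pairs(
    gwas_snps: list[tuple[str, str, int]],
    gene_annotations: list[dict],
    window: int = CIS_WINDOW,
) -> list[tuple[str, str, str]]:
    """(GWAS SNP, gene, exonic SNP) triples within the cis window.

    ``gwas_snps`` holds (snp_id, chrom, pos); each gene annotation is a dict
    with keys ``gene``, ``chrom``, ``tss`` and ``exonic_snps`` (list of SNP
    ids).  A gene is cis to a GWAS SNP when |TSS - pos| <= window
    (boundary inclusive) on the same chromosome.
    """
    triples = []
    for snp_id, chrom, pos in gwas_snps:
        for gene in gene_annotations:
            if gene["chrom"] != chrom:
                continue
            if abs(gene["tss"] - pos) <= window:
                for esnp in gene["exonic_snps"]:
                    triples.append((snp_id, gene["gene"], esnp))
    return triples


# ---------------------------------------------------------------------------
# summary-statistics tables
# ---------------------------------------------------------------------------


def _records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gwas_snp": r.gwas_snp,
                "exonic_snp": r.exonic_snp,
                "gene": r.gene,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "fdr_p": r.fdr_p,
                "n_double_het": r.n_double_het,
                "r_genotype": r.r_genotype,
                "r_allelic": r.r_allelic,
                "category": "" if r.category is None else int(r.category),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_stats(records: list[AssociationRecord], path: str) -> None:
    """Write the association table as TSV with a fixed column order.

    Floating-point columns use repr-exact formatting so that a write/read
    round trip reproduces the records bit-for-bit.
    """
    df = _records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path: str) -> list[AssociationRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"category": "string"}, float_precision="round_trip"
    )
    out = []
    for _, row in df.iterrows():
        cat = row["category"]
        category = None if pd.isna(cat) or cat == "" else int(float(cat))
        out.append(
            AssociationRecord(
                gwas_snp=str(row["gwas_snp"]),
                exonic_snp=str(row["exonic_snp"]),
                gene=str(row["gene"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                p=float(row["p"]),
                fdr_p=float(row["fdr_p"]),
                n_double_het=int(row["n_double_het"]),
                r_genotype=float(row["r_genotype"]),
                r_allelic=float(row["r_allelic"]),
                category=category,
            )
        )
    return out
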