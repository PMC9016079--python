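"""LD summaries, FDR control and the three-way interpretation of aseQTLs.

A significant association between a GWAS SNP and the allelic expression
measured at an exonic proxy SNP is classified by comparing the two SNPs'
own association evidence and their linkage disequilibrium:

* category 1 — the exonic SNP's p-value is less significant than the GWAS
  SNP's, so the GWAS SNP itself (or a variant it tags) is the better
  candidate driver;
* category 2 — the two SNPs are in high LD (|r| > 0.8 in the whole
  sample), so their signals are statistically indistinguishable;
* category 3 — the exonic SNP is more significant and not in high LD:
  the allelic signal points away from the GWAS SNP.

Two different correlations matter.  The genotype correlation is the Pearson
correlation of allele dosages over all subjects.  The allelic correlation
is computed across the phased chromosomes of double-heterozygous subjects
only; it can be +/-1 even when the population LD is nil (with rare alleles
the double-heterozygotes may carry only one of the two possible phase
configurations), which is exactly why a strong allelic association at the
exonic SNP need not implicate the GWAS SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LDSummary",
    "genotype_correlation",
    "allelic_correlation_double_het",
    "classify_category",
    "bh_fdr",
    "ld_summary",
]


@dataclass
class LDSummary:
    r_genotype: float
    r_allelic: float  # NaN when < 2 double-heterozygotes
    p_a: float
    p_b: float
    p_ab: float


def genotype_correlation(dosage_a, dosage_b) -> float:
    """Pearson correlation of allele dosages (0/1/2) over the whole sample.

    Returns NaN when either dosage vector is constant.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two dosage vectors of equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def allelic_correlation_double_het(haplotypes) -> float:
    """Allele-indicator correlation across double-heterozygous chromosomes.

    ``haplotypes`` holds, for each double-heterozygous subject, the two
    phased (gwas_indicator, exonic_indicator) chromosome tuples, with
    indicator 1 for one designated allele at each locus.  The 2 * n_dh
    chromosomes are pooled and the Pearson correlation of the two
    indicators returned; NaN with fewer than two subjects.
    """
    g, e = [], []
    n_subjects = 0
    for chrom_pair in haplotypes:
        n_subjects += 1
        for gi, ei in chrom_pair:
            g.append(float(gi))
            e.append(float(ei))
    if n_subjects < 2:
        return float("nan")
    g = np.asarray(g)
    e = np.asarray(e)
    if np.ptp(g) == 0 or np.ptp(e) == 0:
        return float("nan")
    return float(np.corrcoef(g, e)[0, 1])


def classify_category(p_gwas: float, p_exonic: float | None, r_genotype: float) -> int | None:
    """Three-way interpretation of a significant association.

    Category 1 when the exonic SNP's p-value is strictly less significant
    than the GWAS SNP's; otherwise category 2 when |r_genotype| > 0.8;
    otherwise category 3.  ``None`` when the exonic p-value is missing.
    """
    if p_exonic is None or (isinstance(p_exonic, float) and np.isnan(p_exonic)):
        return None
    if not (0.0 < p_gwas <= 1.0 and 0.0 < p_exonic <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if p_exonic > p_gwas:
        return 1
    if abs(r_genotype) > 0.8:
        return 2
    return 3


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ld_summary(haplotype_table) -> LDSummary:
    """LD summary from a subject table of phased two-locus genotypes.

    Expects columns g1, e1, g2, e2 (minor-allele indicators on haplotypes
    1 and 2, as produced by the haplotype simulator).
    """
    g1 = np.asarray(haplotype_table["g1"], dtype=float)
    g2 = np.asarray(haplotype_table["g2"], dtype=float)
    e1 = np.asarray(haplotype_table["e1"], dtype=float)
    e2 = np.asarray(haplotype_table["e2"], dtype=float)
    dos_g = g1 + g2
    dos_e = e1 + e2
    r_gen = genotype_correlation(dos_g, dos_e)

    dh = (dos_g == 1) & (dos_e == 1)
    pairs = [
        (((g1[i], e1[i])), ((g2[i], e2[i]))) for i in np.flatnonzero(dh)
    ]
    r_all = allelic_correlation_double_het(pairs)

    gs = np.concatenate([g1, g2])
    es = np.concatenate([e1, e2])
    return LDSummary(
        r_genotype=r_gen,
        r_allelic=r_all,
        p_a=float(np.mean(gs)),
        p_b=float(np.mean(es)),
        p_ab=float(np.mean(gs * es)),
    )
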