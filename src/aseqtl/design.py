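"""Allele-pattern coding and construction of the HPMM design.

Two modes are supported.  In *exonic* mode the tested SNP is itself
transcribed: a heterozygote's two allelic counts become paired observations
coded ``X = 1`` (effect allele) and ``X = 0``, each with offset ``l/2``,
while a homozygote contributes its total count with ``X`` in {0, 1} and
offset ``l``.  In *gwas* (haplotype) mode the tested SNP is not transcribed;
its allelic counts are read off the phased haplotypes through a transcribed
proxy SNP, which is only possible for double-heterozygous subjects.  All
other subjects contribute one genotype-level observation coded
``X in {1, 0.5, 0}`` for the three GWAS genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectGenotypes",
    "DesignResult",
    "code_exonic",
    "code_gwas_haplotype",
    "build_design",
]


@dataclass
class SubjectGenotypes:
    """Phased genotypes and allelic counts of one subject at a SNP pair.

    ``exonic_alleles`` / ``gwas_alleles`` are ordered pairs (haplotype 1,
    haplotype 2); the ordering must be consistent across the two loci.
    ``counts`` maps each exonic allele to its read or UMI count.
    """

    subject_id: str
    exonic_alleles: tuple[str, str]
    library_size: float
    counts: dict[str, float] = field(default_factory=dict)
    gwas_alleles: tuple[str, str] | None = None
    phased: bool = True

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValueError(f"{self.subject_id}: library size must be positive")


def code_exonic(
    alleles: tuple[str, str], effect_allele: str, other_allele: str
) -> list[tuple[str, float]]:
    """Allele-pattern coding for a transcribed SNP.

    Returns (pattern, X) tuples: one pattern for a homozygote (X = 1 for the
    effect allele, 0 otherwise), two paired patterns for a heterozygote.
    """
    valid = {effect_allele, other_allele}
    if not set(alleles) <= valid:
        raise ValueError(
            f"multiallelic or unknown genotype {alleles}; expected alleles {valid}"
        )
    a1, a2 = alleles
    if a1 == a2:
        if a1 == effect_allele:
            return [("AA", 1.0)]
        return [("aa", 0.0)]
    return [("A", 1.0), ("a", 0.0)]


def _total_count(sg: SubjectGenotypes) -> float:
    return float(sum(sg.counts.values()))


def code_gwas_haplotype(
    sg: SubjectGenotypes,
    gwas_effect: str,
    gwas_other: str,
) -> list[dict]:
    """Observation skeletons for the haplotype-coded GWAS SNP.

    A double-heterozygous subject is split into two allelic observations:
    the haplotype carrying the effect GWAS allele contributes the count of
    its phased exonic allele with X = 1 and offset l/2, the other haplotype
    with X = 0.  Any other subject contributes its total exonic count with
    X = 1, 0.5 or 0 for GWAS genotypes (effect hom, het, other hom) and
    offset l.
    """
    if sg.gwas_alleles is None:
        raise ValueError(f"{sg.subject_id}: GWAS genotype required in gwas mode")
    valid = {gwas_effect, gwas_other}
    if not set(sg.gwas_alleles) <= valid:
        raise ValueError(
            f"{sg.subject_id}: unknown GWAS alleles {sg.gwas_alleles}; expected {valid}"
        )
    g1, g2 = sg.gwas_alleles
    e1, e2 = sg.exonic_alleles
    gwas_het = g1 != g2
    exonic_het = e1 != e2

    if gwas_het and exonic_het:
        if not sg.phased:
            raise ValueError(
                f"{sg.subject_id}: phase required for a double-heterozygous subject"
            )
        half = sg.library_size / 2.0
        obs = []
        for g, e in ((g1, e1), (g2, e2)):
            x = 1.0 if g == gwas_effect else 0.0
            obs.append(
                {
                    "subject_id": sg.subject_id,
                    "pattern": "A" if x == 1.0 else "a",
                    "exonic_allele": e,
                    "y": float(sg.counts.get(e, 0.0)),
                    "X": x,
                    "K": half,
                }
            )
        obs.sort(key=lambda o: -o["X"])
        return obs

    if gwas_het:
        pattern, x = "Aa", 0.5
    elif g1 == gwas_effect:
        pattern, x = "AA", 1.0
    else:
        pattern, x = "aa", 0.0
    return [
        {
            "subject_id": sg.subject_id,
            "pattern": pattern,
            "exonic_allele": None,
            "y": _total_count(sg),
            "X": x,
            "K": float(sg.library_size),
        }
    ]


@dataclass
class DesignResult:
    """Observations ready for model fitting, with design diagnostics."""

    observations: pd.DataFrame
    n_double_het: int
    untestable: bool
    low_double_het: bool


def build_design(
    subjects: list[SubjectGenotypes],
    mode: str = "exonic",
    effect_allele: str | None = None,
    other_allele: str | None = None,
    covariates: pd.DataFrame | None = None,
    group: pd.Series | None = None,
    min_double_het: int = 3,
) -> DesignResult:
    """Assemble the observation table for one (SNP, gene) analysis.

    ``effect_allele`` / ``other_allele`` name the tested SNP's alleles (the
    exonic SNP in exonic mode, the GWAS SNP in gwas mode); X = 1 corresponds
    to the effect allele.  Subject-level ``covariates`` (indexed by subject
    id) and a binary ``group`` label are replicated across a subject's
    paired observations.  Analyses with fewer than ``min_double_het`` paired
    subjects are flagged but remain fittable.
    """
    if mode not in ("exonic", "gwas"):
        raise ValueError(f"mode must be 'exonic' or 'gwas', got {mode!r}")
    if effect_allele is None or other_allele is None:
        raise ValueError("effect_allele and other_allele are required")

    rows: list[dict] = []
    n_double_het = 0
    for sg in subjects:
        if mode == "exonic":
            patterns = code_exonic(sg.exonic_alleles, effect_allele, other_allele)
            if len(patterns) == 2:
                n_double_het += 1
                half = sg.library_size / 2.0
                e_eff, e_oth = effect_allele, other_allele
                for (pattern, x), allele in zip(patterns, (e_eff, e_oth)):
                    rows.append(
                        {
                            "subject_id": sg.subject_id,
                            "pattern": pattern,
                            "exonic_allele": allele,
                            "y": float(sg.counts.get(allele, 0.0)),
                            "X": x,
                            "K": half,
                        }
                    )
            else:
                pattern, x = patterns[0]
                rows.append(
                    {
                        "subject_id": sg.subject_id,
                        "pattern": pattern,
                        "exonic_allele": None,
                        "y": _total_count(sg),
                        "X": x,
                        "K": float(sg.library_size),
                    }
                )
        else:
            obs = code_gwas_haplotype(sg, effect_allele, other_allele)
            if len(obs) == 2:
                n_double_het += 1
            rows.extend(obs)

    if not rows:
        raise ValueError("no observations: empty subject set")
    df = pd.DataFrame(rows)

    if covariates is not None:
        for col in covariates.columns:
            df[col] = covariates.loc[df["subject_id"], col].to_numpy()
    if group is not None:
        df["D"] = group.loc[df["subject_id"]].to_numpy(dtype=float)

    untestable = bool(np.ptp(df["X"].to_numpy()) == 0)
    return DesignResult(
        observations=df,
        n_double_het=n_double_het,
        untestable=untestable,
        low_double_het=n_double_het < min_double_het,
    )
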