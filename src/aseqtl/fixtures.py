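"""Deterministic toy-data scenarios for every input format.

Each scenario writes a phased VCF, an allelic-count TSV (and for the UMI
scenario a read-level TSV) plus a JSON manifest holding the generating
truth, so that readers, QC and model fitting can be exercised end to end
without external data.  Fixtures are committed as generator code and
seeds, not as files: regenerating a scenario reproduces byte-identical
output.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .simulate import SimConfig, haplotype_frequencies, simulate_ase_dataset

__all__ = ["FixtureSpec", "SCENARIOS", "make_fixture", "list_scenarios"]


@dataclass
class FixtureSpec:
    scenario: str
    seed: int = 20240001
    n_subjects: int = 60
    params: dict = field(default_factory=dict)


SCENARIOS = {
    "null_maf04": "exonic-mode dataset with no allelic effect (beta=0, MAF 0.4)",
    "effect_beta03": "exonic-mode dataset with beta=0.3, MAF 0.4",
    "het_only": "heterozygous subjects only, no overdispersion (beta=0.2)",
    "complete_allelic_corr": (
        "two-SNP scenario without the minor-minor haplotype: double-"
        "heterozygotes show complete allelic correlation despite no LD signal"
    ),
    "umi_toy": "read-level UMI records covering conflict and collapse cases",
}


def list_scenarios() -> dict[str, str]:
    return dict(SCENARIOS)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality score">
##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _write_vcf(path, loci, genotypes, subjects):
    """loci: list of dicts (chrom, pos, id, ref, alt, r2 or None);
    genotypes[locus_index][subject] = (i0, i1, phased)."""
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in dict.fromkeys(l["chrom"] for l in loci):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects)
    )
    for li, locus in enumerate(loci):
        info = "TYPED" if locus.get("r2") is None else f"R2={locus['r2']:.4f}"
        gts = []
        for s in subjects:
            i0, i1, phased = genotypes[li][s]
            sep = "|" if phased else "/"
            gts.append("." if i0 is None else f"{i0}{sep}{i1}")
        lines.append(
            f"{locus['chrom']}\t{locus['pos']}\t{locus['id']}\t{locus['ref']}\t"
            f"{locus['alt']}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    _write_text(path, "\n".join(lines) + "\n")


def _write_text(path, content):
    if os.path.exists(path):
        raise FileExistsError(f"fixture path collision: {path}")
    with open(path, "w") as fh:
        fh.write(content)


def _counts_tsv(rows):
    lines = ["subject_id\tchrom\tpos\tallele\tcount\tlibrary_size"]
    for r in rows:
        lines.append(
            f"{r['subject_id']}\t{r['chrom']}\t{r['pos']}\t{r['allele']}\t"
            f"{r['count']:.0f}\t{r['library_size']:.0f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------


def _exonic_scenario(spec: FixtureSpec, outdir, beta, maf, var_eps=0.5, het_only=False):
    cfg = SimConfig(
        n_subjects=spec.n_subjects,
        maf=maf,
        beta=beta,
        var_eps=var_eps,
        library_size=1e5,
        mean_count=80.0,
        seed=spec.seed,
        **spec.params,
    )
    rng = np.random.default_rng(cfg.seed)
    obs = simulate_ase_dataset(cfg, rng)
    if het_only:
        sizes = obs.groupby("subject_id")["y"].transform("size")
        obs = obs[sizes == 2].reset_index(drop=True)

    chrom, pos = "1", 1_000_000
    ref, alt = "C", "T"  # effect allele = ref (X=1 pattern)
    subjects = sorted(obs["subject_id"].unique())
    genotypes = {0: {}}
    count_rows = []
    for sid in subjects:
        grp = obs[obs["subject_id"] == sid]
        if len(grp) == 2:
            genotypes[0][sid] = (0, 1, True)
            for _, row in grp.iterrows():
                allele = ref if row["X"] == 1.0 else alt
                count_rows.append(
                    dict(
                        subject_id=sid,
                        chrom=chrom,
                        pos=pos,
                        allele=allele,
                        count=row["y"],
                        library_size=cfg.library_size,
                    )
                )
        else:
            x = grp["X"].iloc[0]
            gt = (0, 0) if x == 1.0 else (1, 1)
            genotypes[0][sid] = (*gt, True)
            allele = ref if x == 1.0 else alt
            count_rows.append(
                dict(
                    subject_id=sid,
                    chrom=chrom,
                    pos=pos,
                    allele=allele,
                    count=grp["y"].iloc[0],
                    library_size=cfg.library_size,
                )
            )

    loci = [dict(chrom=chrom, pos=pos, id="rsEX1", ref=ref, alt=alt, r2=0.99)]
    _write_vcf(os.path.join(outdir, "genotypes.vcf"), loci, genotypes, subjects)
    _write_text(os.path.join(outdir, "counts.tsv"), _counts_tsv(count_rows))
    return {
        "truth": {
            "beta": beta,
            "maf": maf,
            "var_b": cfg.var_b,
            "var_eps": var_eps,
            "mu": cfg.resolved_mu(),
            "library_size": cfg.library_size,
            "effect_allele": ref,
            "other_allele": alt,
            "n_het": int((obs.groupby("subject_id").size() == 2).sum()),
        },
        "files": ["genotypes.vcf", "counts.tsv"],
    }


def _complete_allelic_corr_scenario(spec: FixtureSpec, outdir):
    """Two SNPs, rare minor alleles, minor-minor haplotype absent.

    Every double-heterozygote is phased (A-b, a-B): the allelic correlation
    in double-heterozygotes is exactly -1 although the haplotype table has
    no more association than independence would produce.
    """
    maf = 0.05
    # haplotype correlation at the lower feasibility bound removes 'ab'
    denom = math.sqrt(maf * (1 - maf)) ** 2
    ld_r = -maf * maf / denom
    freqs = haplotype_frequencies(maf, maf, ld_r)
    assert abs(freqs["ab"]) < 1e-12

    n = spec.n_subjects
    rng = np.random.default_rng(spec.seed)
    haps = ["AB", "Ab", "aB"]
    p = np.array([freqs[h] for h in haps])
    p = p / p.sum()
    draws = rng.choice(3, size=(n, 2), p=p)

    chrom = "2"
    gwas = dict(chrom=chrom, pos=500_000, id="rsGWAS1", ref="A", alt="G", r2=0.99)
    exon = dict(chrom=chrom, pos=760_000, id="rsEX2", ref="T", alt="C", r2=0.98)
    subjects = [f"S{i:04d}" for i in range(n)]
    genotypes = {0: {}, 1: {}}
    for i, sid in enumerate(subjects):
        g_idx = tuple(int(h == 2) for h in draws[i])  # 1 = minor GWAS allele a
        e_idx = tuple(int(h == 1) for h in draws[i])  # 1 = minor exonic allele b
        genotypes[0][sid] = (*g_idx, True)
        genotypes[1][sid] = (*e_idx, True)
    _write_vcf(os.path.join(outdir, "genotypes.vcf"), [gwas, exon], genotypes, subjects)

    n_dh = sum(
        1
        for i in range(n)
        if {draws[i, 0], draws[i, 1]} == {1, 2}  # Ab + aB
    )
    return {
        "truth": {
            "maf_gwas": maf,
            "maf_exonic": maf,
            "haplotype_freqs": freqs,
            "ld_r": ld_r,
            "r_allelic_double_het": -1.0,
            "n_double_het": n_dh,
        },
        "files": ["genotypes.vcf"],
    }


def _umi_toy_scenario(spec: FixtureSpec, outdir):
    rows = [
        # cell, umi, chrom, pos, allele, n_reads, transcript_assigned
        ("CELL1", "AAAA", "1", 1000, "A", 3, 1),  # clean UMI
        ("CELL1", "AAAT", "1", 1000, "A", 1, 1),  # collapses into AAAA
        ("CELL1", "CCCC", "1", 1000, "G", 2, 1),  # second allele
        ("CELL1", "GGGG", "1", 1000, "A", 1, 1),
        ("CELL1", "GGGG", "1", 1000, "G", 1, 1),  # conflicting UMI: removed
        ("CELL1", "TTTT", "1", 1000, "A", 1, 0),  # not assigned to transcript
        ("CELL2", "AAAA", "1", 1000, "G", 2, 1),  # same UMI, different cell
    ]
    lines = ["cell_barcode\tumi\tchrom\tpos\tallele\tn_reads\ttranscript_assigned"]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    _write_text(os.path.join(outdir, "reads.tsv"), "\n".join(lines) + "\n")
    barcodes = [
        "cell_barcode\tsubject_id\tcell_type",
        "CELL1\tSUBJ1\tneuron",
        "CELL2\tSUBJ1\tneuron",
    ]
    _write_text(os.path.join(outdir, "barcodes.tsv"), "\n".join(barcodes) + "\n")
    return {
        "truth": {
            # CELL1: AAAA+AAAT collapse -> one A call; CCCC -> one G call;
            # GGGG conflicts; TTTT unassigned.  CELL2: one G call.
            "expected_counts": {"A": 1, "G": 2},
        },
        "files": ["reads.tsv", "barcodes.tsv"],
    }


def make_fixture(spec: FixtureSpec, outdir: str) -> dict:
    """Materialise a scenario; returns (and writes) its manifest."""
    if spec.scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {spec.scenario!r}; available: {sorted(SCENARIOS)}"
        )
    os.makedirs(outdir, exist_ok=True)
    if spec.scenario == "null_maf04":
        body = _exonic_scenario(spec, outdir, beta=0.0, maf=0.4)
    elif spec.scenario == "effect_beta03":
        body = _exonic_scenario(spec, outdir, beta=0.3, maf=0.4)
    elif spec.scenario == "het_only":
        body = _exonic_scenario(
            spec, outdir, beta=0.2, maf=0.5, var_eps=0.0, het_only=True
        )
    elif spec.scenario == "complete_allelic_corr":
        body = _complete_allelic_corr_scenario(spec, outdir)
    else:
        body = _umi_toy_scenario(spec, outdir)

    manifest = {"spec": asdict(spec), **body}
    _write_text(
        os.path.join(outdir, "manifest.json"),
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
    )
    return manifest
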