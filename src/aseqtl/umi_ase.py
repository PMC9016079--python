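"""UMI-level allele-specific quantification for droplet snRNA-seq.

Within one cell and exonic locus, each UMI's reads are reduced to a single
allele call: reads not assigned to a transcript are ignored, and a UMI whose
remaining reads disagree on the allele is discarded as a likely sequencing
error.  Surviving UMIs are then collapsed at Hamming distance <= 1
(directional: the UMI with fewer supporting reads is absorbed into the one
with more, ties broken lexicographically); a collapsed group whose members
carry different alleles is discarded for the same reason.  Allele counts
are the number of collapsed UMIs per allele, aggregated over all cells of
the same subject and cell type into pseudo-bulk allelic counts.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .io_qc import AllelicCountRecord, Locus

logger = logging.getLogger(__name__)

__all__ = [
    "ReadLevelRecord",
    "UmiAlleleCall",
    "call_umi_alleles",
    "collapse_umis",
    "aggregate_to_subject",
    "quantify_ase",
]

_NUCS = set("ACGT")


@dataclass(frozen=True)
class ReadLevelRecord:
    """Reads sharing a (cell, UMI, locus, allele) combination."""

    cell_barcode: str
    umi: str
    exonic_locus: Locus
    allele: str
    n_reads: int = 1
    transcript_assigned: bool = True

    def __post_init__(self):
        if not set(self.umi) <= _NUCS:
            raise ValueError(f"UMI {self.umi!r} has non-ACGT characters")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass(frozen=True)
class UmiAlleleCall:
    """Consensus allele of one surviving UMI in one cell."""

    cell_barcode: str
    exonic_locus: Locus
    umi: str
    allele: str
    n_reads: int = 1


def call_umi_alleles(records: list[ReadLevelRecord]) -> list[UmiAlleleCall]:
    """Per-UMI allele calls for the reads of one cell at one locus.

    Reads without a transcript assignment are dropped; a UMI whose reads
    carry different alleles is removed entirely.
    """
    if not records:
        return []
    cells = {r.cell_barcode for r in records}
    loci = {r.exonic_locus for r in records}
    if len(cells) > 1 or len(loci) > 1:
        raise ValueError("records must share one cell barcode and one locus")
    by_umi: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in records:
        if not r.transcript_assigned:
            continue
        by_umi[r.umi][r.allele] += r.n_reads
    cell = next(iter(cells))
    locus = next(iter(loci))
    calls = []
    for umi in sorted(by_umi):
        alleles = by_umi[umi]
        if len(alleles) != 1:
            continue  # conflicting alleles: presumed sequencing error
        allele, n = next(iter(alleles.items()))
        calls.append(UmiAlleleCall(cell, locus, umi, allele, n))
    return calls


def _hamming1(u: str, v: str) -> bool:
    mismatches = 0
    for x, y in zip(u, v):
        if x != y:
            mismatches += 1
            if mismatches > 1:
                return False
    return True


def collapse_umis(calls: list[UmiAlleleCall]) -> list[UmiAlleleCall]:
    """Collapse UMI calls of one cell x locus at Hamming distance <= 1.

    Processing order is by decreasing read support (ties lexicographic);
    each UMI is absorbed into the best-supported existing group whose
    representative is within one mismatch.  A group whose members disagree
    on the allele is removed.
    """
    if not calls:
        return []
    lengths = {len(c.umi) for c in calls}
    if len(lengths) > 1:
        raise ValueError(f"UMIs of unequal length: {sorted(lengths)}")
    ordered = sorted(calls, key=lambda c: (-c.n_reads, c.umi))
    groups: list[dict] = []  # rep call, members, total reads
    for c in ordered:
        target = None
        for grp in groups:
            if _hamming1(c.umi, grp["rep"].umi):
                if target is None or grp["reads"] > target["reads"]:
                    target = grp
        if target is None:
            groups.append({"rep": c, "members": [c], "reads": c.n_reads})
        else:
            target["members"].append(c)
            target["reads"] += c.n_reads
    out = []
    for grp in groups:
        alleles = {m.allele for m in grp["members"]}
        if len(alleles) != 1:
            continue  # collapsed group unites conflicting alleles
        rep = grp["rep"]
        out.append(
            UmiAlleleCall(
                rep.cell_barcode, rep.exonic_locus, rep.umi, rep.allele, grp["reads"]
            )
        )
    return out


def aggregate_to_subject(
    calls: list[UmiAlleleCall],
    barcode_map: pd.DataFrame,
    library_sizes: dict | None = None,
) -> list[AllelicCountRecord]:
    """Pseudo-bulk allelic counts per (subject, cell type, locus).

    ``barcode_map`` has columns cell_barcode, subject_id, cell_type; a
    barcode mapped to two different subjects or cell types is an error, and
    calls from unmapped barcodes are dropped (their number is logged).
    Counts are numbers of collapsed UMIs sharing each allele.  Library
    sizes default to the subject x cell-type total UMI count unless
    supplied via ``library_sizes`` (keyed by (subject_id, cell_type)).
    """
    dups = barcode_map.groupby("cell_barcode").nunique()
    bad = dups[(dups["subject_id"] > 1) | (dups["cell_type"] > 1)]
    if len(bad):
        raise ValueError(
            f"conflicting barcode assignments for {list(bad.index[:5])}"
        )
    mapping = {
        row.cell_barcode: (row.subject_id, row.cell_type)
        for row in barcode_map.itertuples()
    }
    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    n_unmapped = 0
    for c in calls:
        target = mapping.get(c.cell_barcode)
        if target is None:
            n_unmapped += 1
            continue
        subject, cell_type = target
        counts[(subject, cell_type, c.exonic_locus)][c.allele] += 1
    if n_unmapped:
        logger.info("dropped %d calls from unmapped barcodes", n_unmapped)

    totals: dict[tuple, int] = defaultdict(int)
    for (subject, cell_type, _locus), by_allele in counts.items():
        totals[(subject, cell_type)] += sum(by_allele.values())

    out = []
    for (subject, cell_type, locus), by_allele in sorted(
        counts.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
    ):
        if library_sizes is not None:
            lib = library_sizes[(subject, cell_type)]
        else:
            lib = totals[(subject, cell_type)]
        out.append(
            AllelicCountRecord(
                subject_id=subject,
                exonic_locus=locus,
                count_by_allele=dict(by_allele),
                library_size=float(lib),
                cell_type=cell_type,
            )
        )
    return out


def quantify_ase(
    reads: list[ReadLevelRecord],
    barcode_map: pd.DataFrame,
    library_sizes: dict | None = None,
) -> list[AllelicCountRecord]:
    """Full pipeline: per-UMI calls, one-mismatch collapsing, pseudo-bulk."""
    by_cell_locus: dict[tuple, list[ReadLevelRecord]] = defaultdict(list)
    for r in reads:
        by_cell_locus[(r.cell_barcode, r.exonic_locus)].append(r)
    all_calls: list[UmiAlleleCall] = []
    for key in sorted(by_cell_locus, key=lambda k: (k[0], str(k[1]))):
        calls = call_umi_alleles(by_cell_locus[key])
        all_calls.extend(collapse_umis(calls))
    return aggregate_to_subject(all_calls, barcode_map, library_sizes)
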