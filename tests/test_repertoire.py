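"""Clonotype calling, expansion ranking, overlap statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from synoclone.datatypes import ClusterAssignment, SynocloneError
from synoclone.repertoire import (
    call_clonotypes,
    clonal_fraction,
    clone_cluster_membership,
    overlap_matrix,
    overlap_test,
    top_expanded,
    universe_size_of,
)
from synoclone.stats import bh_adjust, fisher_enrichment_p


def contig_row(barcode, chain="TRA", v="TRAV1", j="TRAJ1", nt="TGTGCA", aa="CA", prod=True):
    return {
        "barcode": barcode,
        "chain": chain,
        "v_gene": v,
        "j_gene": j,
        "cdr3_nt": nt,
        "cdr3_aa": aa,
        "productive": prod,
        "umis": 3,
    }


def contigs_of(rows):
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clonotype calling
# ---------------------------------------------------------------------------

def test_singleton_paired_cell_forms_one_clone():
    rows = [
        contig_row("c1", "TRA"),
        contig_row("c1", "TRB", v="TRBV1", j="TRBJ1", nt="TGTTTT", aa="CF"),
    ]
    table = call_clonotypes(contigs_of(rows))
    assert table.n_clones == 1
    assert table.members(table.clones["clone_id"].iloc[0]) == ["c1"]


def test_nonproductive_contigs_are_ignored_for_identity():
    base = [
        contig_row("c1", "TRA"),
        contig_row("c1", "TRB", v="TRBV1", j="TRBJ1", nt="TGTTTT", aa="CF"),
    ]
    extra = [
        contig_row("c2", "TRA"),
        contig_row("c2", "TRB", v="TRBV1", j="TRBJ1", nt="TGTTTT", aa="CF"),
        contig_row("c2", "TRB", v="TRBV9", j="TRBJ9", nt="TGTAAA", aa="CK", prod=False),
    ]
    table = call_clonotypes(contigs_of(base + extra))
    assert table.n_clones == 1
    assert set(table.cell_to_clone.index) == {"c1", "c2"}


def test_multi_chain_cells_form_distinct_clones():
    single = [contig_row("c1", "TRA")]
    double = [contig_row("c2", "TRA"), contig_row("c2", "TRA", v="TRAV9", nt="TGTCCC", aa="CP")]
    table = call_clonotypes(contigs_of(single + double))
    assert table.n_clones == 2


def test_cells_without_productive_chains_are_absent():
    rows = [contig_row("c1", prod=False)]
    table = call_clonotypes(contigs_of(rows))
    assert table.n_clones == 0
    assert len(table.cell_to_clone) == 0


def test_grouping_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    rows = []
    planted = {}
    sigs = [("TRAV%d" % i, "TGT" + "ACG" * i) for i in range(1, 5)]
    for i in range(10):
        v, nt = sigs[rng.integers(0, 4)]
        planted[f"cell{i}"] = (v, nt)
        rows.append(contig_row(f"cell{i}", v=v, nt=nt))
    table = call_clonotypes(contigs_of(rows))
    # brute force: group barcodes by signature
    expected = {}
    for bc, sig in planted.items():
        expected.setdefault(sig, set()).add(bc)
    got = {
        frozenset(table.members(cid)) for cid in table.clones["clone_id"]
    }
    assert got == {frozenset(v) for v in expected.values()}


# ---------------------------------------------------------------------------
# clonal fraction
# ---------------------------------------------------------------------------

def _meta(mapping):
    return pd.DataFrame(
        {"sample_id": pd.Series(mapping)}, index=pd.Index(list(mapping), name="barcode")
    )


def test_clonal_fraction_arithmetic_and_normalization():
    rows = []
    for i in range(5):
        rows.append(contig_row(f"a{i}", nt="TGTAAA"))
    for i in range(45):
        rows.append(contig_row(f"b{i}", nt="TGT" + "CCC" * (i + 1)))
    table = call_clonotypes(contigs_of(rows))
    meta = _meta({bc: "S1" for bc in table.cell_to_clone.index})
    frac = clonal_fraction(table, meta, "S1")
    big = table.cell_to_clone["a0"]
    assert frac[big] == pytest.approx(0.1)
    assert frac.sum() == pytest.approx(1.0)


def test_single_clone_sample_fraction_is_one():
    table = call_clonotypes(contigs_of([contig_row("c1")]))
    frac = clonal_fraction(table, _meta({"c1": "S"}), "S")
    assert list(frac) == [1.0]


def test_unknown_sample_errors():
    table = call_clonotypes(contigs_of([contig_row("c1")]))
    with pytest.raises(SynocloneError, match="S9"):
        clonal_fraction(table, _meta({"c1": "S"}), "S9")


# ---------------------------------------------------------------------------
# top expanded clones
# ---------------------------------------------------------------------------

def _assignment(mapping):
    return ClusterAssignment(labels=pd.Series(mapping), round_id="r")


def test_top_expanded_returns_all_when_n_exceeds_population():
    rows = [contig_row(f"c{i}", nt="TGT" + "AAA" * (i + 1)) for i in range(3)]
    table = call_clonotypes(contigs_of(rows))
    asn = _assignment({f"c{i}": "X" for i in range(3)})
    ranked, mat = top_expanded(table, asn, n=100)
    assert len(ranked) == 3
    assert mat.shape == (3, 1)


def test_tie_break_prefers_larger_total_count():
    rows = []
    # clone A: 2 cells in PB, 3 elsewhere (total 5); clone B: 2 cells in PB only
    for i in range(2):
        rows.append(contig_row(f"pa{i}", nt="TGTAAA"))
        rows.append(contig_row(f"pb{i}", nt="TGTCCC"))
    for i in range(3):
        rows.append(contig_row(f"sa{i}", nt="TGTAAA"))
    table = call_clonotypes(contigs_of(rows))
    meta = pd.DataFrame(
        {
            "compartment": ["PB"] * 4 + ["SF"] * 3,
            "sample_id": ["P1_PB"] * 4 + ["P1_SF"] * 3,
        },
        index=pd.Index(["pa0", "pb0", "pa1", "pb1", "sa0", "sa1", "sa2"], name="barcode"),
    ).reindex(table.cell_to_clone.index)
    asn = _assignment({bc: "X" for bc in table.cell_to_clone.index})
    ranked, _ = top_expanded(table, asn, meta, n=2, scope="per_compartment")
    pb = ranked[ranked["group"] == "PB"].sort_values("rank")
    clone_a = table.cell_to_clone["pa0"]
    assert pb.iloc[0]["clone_id"] == clone_a  # tie at 2 cells; A has 5 total


def test_top_expanded_rejects_nonpositive_n():
    table = call_clonotypes(contigs_of([contig_row("c1")]))
    with pytest.raises(SynocloneError):
        top_expanded(table, _assignment({"c1": "X"}), n=0)


# ---------------------------------------------------------------------------
# overlap matrix
# ---------------------------------------------------------------------------

def test_disjoint_clusters_have_zero_off_diagonal():
    mem = {"A": {"c1", "c2"}, "B": {"c3"}}
    mat = overlap_matrix(mem)
    assert mat.loc["A", "B"] == 0
    assert mat.loc["A", "A"] == 2
    assert mat.loc["B", "B"] == 1


def test_identical_clone_sets_share_everything():
    mem = {"A": {"x", "y", "z"}, "B": {"x", "y", "z"}}
    mat = overlap_matrix(mem)
    assert mat.loc["A", "B"] == 3


def test_planted_sharing_equals_set_intersection(demo, truth_assignment):
    _, contigs, truth = demo
    table = call_clonotypes(contigs)
    mat = overlap_matrix(table, truth_assignment)
    mem = clone_cluster_membership(table, truth_assignment)
    expected = len(mem["CX3CR1hi_CD8T"] & mem["CXCR3hi_CD8T"])
    assert mat.loc["CX3CR1hi_CD8T", "CXCR3hi_CD8T"] == expected
    assert expected >= 20  # planted shared clones all present


# ---------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(shared, n_a, n_b, universe):
    """Exact upper tail by direct enumeration with rational arithmetic."""
    total = math.comb(universe, n_b)
    acc = Fraction(0)
    for x in range(shared, min(n_a, n_b) + 1):
        if n_b - x > universe - n_a:
            continue
        acc += Fraction(math.comb(n_a, x) * math.comb(universe - n_a, n_b - x), total)
    return float(acc)


def test_zero_overlap_gives_p_one():
    mat = overlap_matrix({"A": {"x"}, "B": {"y"}})
    res = overlap_test(mat, universe_size=10)
    assert res["p_one_sided"].iloc[0] == 1.0


def test_fisher_p_matches_enumeration_oracle_example():
    p = fisher_enrichment_p(5, 10, 8, 20)
    assert p == pytest.approx(hypergeom_tail_oracle(5, 10, 8, 20), abs=1e-12)


def test_bh_step_up_example():
    q = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])


def test_invariant_violation_rejected():
    with pytest.raises(SynocloneError):
        fisher_enrichment_p(6, 5, 8, 20)


@given(
    universe=hst.integers(min_value=2, max_value=30),
    data=hst.data(),
)
@settings(max_examples=200, deadline=None)
def test_fisher_matches_oracle_on_random_small_tables(universe, data):
    n_a = data.draw(hst.integers(min_value=1, max_value=universe))
    n_b = data.draw(hst.integers(min_value=1, max_value=universe))
    lo = max(0, n_a + n_b - universe)
    shared = data.draw(hst.integers(min_value=lo, max_value=min(n_a, n_b)))
    p = fisher_enrichment_p(shared, n_a, n_b, universe)
    assert p == pytest.approx(hypergeom_tail_oracle(shared, n_a, n_b, universe), abs=1e-12)


@given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=50))
@settings(max_examples=200, deadline=None)
def test_bh_properties(pvals):
    q = bh_adjust(pvals)
    assert (q >= np.asarray(pvals) - 1e-15).all()
    assert (q <= 1.0 + 1e-15).all()
    # order invariance
    perm = np.argsort(pvals)[::-1]
    q_perm = bh_adjust(np.asarray(pvals)[perm])
    assert np.allclose(q_perm, q[perm])
    # monotone in p-rank
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_universe_size_from_table_and_membership(demo, truth_assignment):
    _, contigs, _ = demo
    table = call_clonotypes(contigs)
    mem = clone_cluster_membership(table, truth_assignment)
    assert universe_size_of(table) == table.n_clones
    # every clone has >=1 cell in some cluster, so membership covers all
    assert universe_size_of(mem) == table.n_clones
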