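"""Normalization, clustering, marker and composition contracts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from sklearn.metrics import adjusted_rand_score

from synoclone.datatypes import ClusterAssignment, SynocloneError
from synoclone.phenotype import (
    ClusteringParams,
    MarkerRule,
    annotate_clusters,
    cluster_cells,
    compartment_composition,
    find_markers,
    normalize_log,
    subcluster,
)
from synoclone.synthetic import ClusterSpec, generate_dataset

from conftest import make_matrix


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_single_gene_cell_normalizes_to_log2_of_scale_plus_one():
    m = make_matrix([[100], [0]], ["A", "B"])
    norm = normalize_log(m, scale=1e4)
    assert norm.values[0, 0] == pytest.approx(math.log2(10001))
    assert norm.values[1, 0] == 0.0


def test_all_zero_gene_stays_zero(demo_clean):
    matrix, _, _ = demo_clean
    norm = normalize_log(matrix)
    dense_raw = np.asarray(matrix.counts.todense())
    dense_norm = np.asarray(norm.values.todense())
    zero_genes = dense_raw.sum(axis=1) == 0
    assert (dense_norm[zero_genes] == 0).all()


def test_normalization_equals_dense_oracle(demo_clean):
    matrix, _, _ = demo_clean
    norm = normalize_log(matrix)
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    expected = np.log2(dense / np.maximum(totals, 1) * 1e4 + 1)
    np.testing.assert_allclose(np.asarray(norm.values.todense()), expected, rtol=1e-10)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _two_block_norm(seed=0, n=60):
    # strong, low-dispersion signatures: a cleanly separable toy case
    specs = [
        ClusterSpec("A", n // 2, [f"A{i}" for i in range(8)], signature_mean=20, dispersion=10),
        ClusterSpec("B", n // 2, [f"B{i}" for i in range(8)], signature_mean=20, dispersion=10),
    ]
    m, _, truth = generate_dataset(specs, n_patients=1, seed=seed)
    return normalize_log(m), truth


def test_two_separable_blocks_give_two_clusters():
    norm, truth = _two_block_norm()
    asn = cluster_cells(norm, ClusteringParams(n_pcs=10, k_neighbors=5, resolution=0.6))
    assert len(asn.cluster_names) == 2
    truth_labels = [truth.cell_cluster[b] for b in norm.barcodes]
    assert adjusted_rand_score(truth_labels, asn.labels.to_numpy()) == 1.0


def test_partition_invariant_to_cell_order():
    norm, _ = _two_block_norm(seed=3)
    asn1 = cluster_cells(norm, ClusteringParams(n_pcs=10, k_neighbors=5, seed=1))
    rng = np.random.default_rng(0)
    perm = rng.permutation(norm.n_cells)
    shuffled = norm.subset_cells([norm.barcodes[i] for i in perm])
    asn2 = cluster_cells(shuffled, ClusteringParams(n_pcs=10, k_neighbors=5, seed=1))
    merged = pd.concat(
        [asn1.labels.rename("a"), asn2.labels.rename("b")], axis=1
    )
    # identical partition with identical canonical labels
    assert (merged["a"] == merged["b"]).all()


def test_small_input_reduces_pcs_with_warning(caplog):
    norm, _ = _two_block_norm(n=20)
    with caplog.at_level("WARNING"):
        asn = cluster_cells(norm, ClusteringParams(n_pcs=40, k_neighbors=5))
    assert "reducing n_pcs" in caplog.text
    assert len(asn.labels) == 20


def test_subcluster_recovers_planted_subtypes():
    specs = [
        ClusterSpec("T1", 30, [f"X{i}" for i in range(8)], signature_mean=20, dispersion=10),
        ClusterSpec("T2", 30, [f"Y{i}" for i in range(8)], signature_mean=20, dispersion=10),
        ClusterSpec("M", 30, [f"Z{i}" for i in range(8)], signature_mean=20, dispersion=10),
    ]
    m, _, truth = generate_dataset(specs, n_patients=1, seed=4)
    norm = normalize_log(m)
    # pretend round 1 merged T1+T2 into one parent cluster
    parent = pd.Series(
        ["T" if truth.cell_cluster[b] in ("T1", "T2") else "M" for b in norm.barcodes],
        index=norm.barcodes,
    )
    asn = ClusterAssignment(labels=parent, round_id="major")
    sub = subcluster(
        norm, asn, ["T"], ClusteringParams(n_pcs=10, k_neighbors=5, resolution=0.6, round_id="sub")
    )
    truth_sub = [truth.cell_cluster[b] for b in sub.labels.index]
    assert adjusted_rand_score(truth_sub, sub.labels.to_numpy()) == 1.0
    assert all(lab.startswith("sub:") for lab in sub.labels)


def test_subcluster_of_everything_equals_full_clustering():
    norm, _ = _two_block_norm(seed=5)
    params = ClusteringParams(n_pcs=10, k_neighbors=5, seed=2, round_id="sub")
    full = cluster_cells(norm, params)
    asn = ClusterAssignment(
        labels=pd.Series("all", index=pd.Index(norm.barcodes)), round_id="major"
    )
    sub = subcluster(norm, asn, ["all"], params)
    assert (sub.labels.str.removeprefix("sub:") == full.labels).all()


def test_subcluster_empty_selection_errors():
    norm, _ = _two_block_norm()
    asn = ClusterAssignment(
        labels=pd.Series("all", index=pd.Index(norm.barcodes)), round_id="major"
    )
    with pytest.raises(SynocloneError):
        subcluster(norm, asn, [], ClusteringParams(n_pcs=5, k_neighbors=5))


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def test_perfect_marker_ranks_top_with_zero_pct_out():
    counts = np.zeros((3, 100), dtype=int)
    counts[0, :50] = 5  # marker of cluster A only
    counts[1, :] = 3  # ubiquitous
    counts[2, 50:] = 4  # marker of cluster B
    m = make_matrix(counts, ["MARK_A", "UBIQ", "MARK_B"])
    norm = normalize_log(m)
    labels = pd.Series(["A"] * 50 + ["B"] * 50, index=norm.barcodes)
    res = find_markers(norm, ClusterAssignment(labels=labels, round_id="r"))
    top_a = res[res["cluster"] == "A"].iloc[0]
    assert top_a["gene"] == "MARK_A"
    assert top_a["pct_out"] == 0.0


def test_ranksum_p_matches_exact_permutation_enumeration():
    """6+6 cells, one gene: p equals enumeration over all 12!/(6!6!) splits."""
    values = np.array([0.1, 0.5, 0.9, 1.3, 1.8, 2.2, 2.9, 3.1, 3.8, 4.4, 5.0, 5.6])
    in_mask = np.zeros(12, dtype=bool)
    in_mask[[0, 1, 2, 3, 8, 9]] = True

    counts = np.zeros((2, 12))
    counts[0] = values * 10
    counts[1] = 100  # constant library anchor
    m = make_matrix(counts.astype(int), ["GENE", "ANCHOR"])
    norm = normalize_log(m)
    labels = pd.Series(np.where(in_mask, "A", "B"), index=norm.barcodes)
    res = find_markers(norm, ClusterAssignment(labels=labels, round_id="r"))
    p_impl = res[(res["gene"] == "GENE") & (res["cluster"] == "A")]["p_value"].iloc[0]

    # enumeration oracle on the normalized values
    x = np.asarray(norm.values.todense())[0]
    obs = st.rankdata(x)[in_mask].sum()
    null = [
        st.rankdata(x)[list(combo)].sum()
        for combo in itertools.combinations(range(12), 6)
    ]
    null = np.array(null)
    mu = null.mean()
    p_oracle = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-12)
    assert p_impl == pytest.approx(p_oracle, abs=1e-12)


def test_bh_q_values_dominate_p_and_are_monotone(demo_clean, truth_assignment=None):
    matrix, _, truth = demo_clean
    norm = normalize_log(matrix)
    labels = pd.Series({b: truth.cell_cluster[b] for b in norm.barcodes})
    res = find_markers(norm, ClusterAssignment(labels=labels.loc[norm.barcodes], round_id="t"))
    assert (res["q_value"] >= res["p_value"] - 1e-15).all()
    by_p = res.sort_values("p_value")
    assert by_p["q_value"].is_monotonic_increasing


def test_tiny_cluster_skipped_with_warning():
    counts = np.ones((2, 12), dtype=int) * 3
    m = make_matrix(counts, ["A", "B"])
    norm = normalize_log(m)
    labels = pd.Series(["X"] * 10 + ["Y"] * 2, index=norm.barcodes)
    with pytest.warns(UserWarning, match="cluster Y"):
        find_markers(norm, ClusterAssignment(labels=labels, round_id="r"))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _marker_table(rows):
    return pd.DataFrame(
        rows, columns=["gene", "cluster", "log2_fc", "pct_in", "pct_out", "p_value", "q_value"]
    )


def test_annotation_rule_matching_and_fallbacks():
    markers = _marker_table(
        [
            ("CD3D", "0", 2.0, 0.9, 0.1, 1e-9, 1e-8),
            ("CD8A", "0", 1.5, 0.8, 0.1, 1e-9, 1e-8),
            ("CD19", "1", 2.0, 0.9, 0.1, 1e-9, 1e-8),
            ("MS4A1", "1", 2.0, 0.9, 0.1, 1e-9, 1e-8),
            ("PPBP", "2", 2.0, 0.9, 0.1, 1e-9, 1e-8),
        ]
    )
    rules = [
        MarkerRule("T-CD8", required=["CD3D", "CD8A"]),
        MarkerRule("B", required=["CD19"]),
        MarkerRule("B-mem", required=["MS4A1"]),
    ]
    out = annotate_clusters(markers, rules)
    assert out["0"] == "T-CD8"
    assert out["1"] == "ambiguous"  # matches both B rules
    assert out["2"] == "unassigned"


def test_annotation_respects_forbidden_genes():
    markers = _marker_table(
        [
            ("CD3D", "0", 2.0, 0.9, 0.1, 1e-9, 1e-8),
            ("CD14", "0", 2.0, 0.9, 0.1, 1e-9, 1e-8),
        ]
    )
    rules = [MarkerRule("T", required=["CD3D"], forbidden=["CD14"])]
    assert annotate_clusters(markers, rules)["0"] == "unassigned"


def test_duplicate_rule_labels_rejected():
    with pytest.raises(SynocloneError, match="duplicate"):
        annotate_clusters(_marker_table([]), [MarkerRule("X", ["A"]), MarkerRule("X", ["B"])])


def test_truth_lineages_annotated_correctly(demo_clean):
    matrix, _, truth = demo_clean
    norm = normalize_log(matrix)
    labels = pd.Series({b: truth.cell_cluster[b] for b in norm.barcodes})
    markers = find_markers(norm, ClusterAssignment(labels=labels.loc[norm.barcodes], round_id="t"))
    rules = [
        MarkerRule("NaiveT", ["TCF7", "SELL"]),
        MarkerRule("CX3CR1hi_CD8T", ["FGFBP2", "GZMH"]),
        MarkerRule("CXCR3hi_CD8T", ["GZMK", "CD27"]),
        MarkerRule("Treg", ["FOXP3", "IL2RA"]),
        MarkerRule("Myeloid", ["CD14", "LYZ"]),
        MarkerRule("B", ["CD19", "MS4A1"]),
    ]
    out = annotate_clusters(markers, rules)
    assert out == {name: name for name in out}


# ---------------------------------------------------------------------------
# compartment composition
# ---------------------------------------------------------------------------

def _composition_inputs(fracs_by_patient):
    """Build an assignment + metadata with exact per-sample fractions."""
    rows_meta, labels = [], []
    barcode_i = 0
    for patient, comps in fracs_by_patient.items():
        for comp, cluster_counts in comps.items():
            sample = f"{patient}_{comp}"
            for cluster, k in cluster_counts.items():
                for _ in range(k):
                    bc = f"b{barcode_i}"
                    barcode_i += 1
                    rows_meta.append((bc, patient, comp, sample))
                    labels.append((bc, cluster))
    meta = pd.DataFrame(
        rows_meta, columns=["barcode", "patient", "compartment", "sample_id"]
    ).set_index("barcode")
    ser = pd.Series(dict(labels))
    return ClusterAssignment(labels=ser, round_id="r"), meta


def test_identical_fractions_give_null_t_test():
    layout = {
        f"P{i}": {
            "PB": {"c1": 5, "c2": 5},
            "SF": {"c1": 5, "c2": 5},
        }
        for i in range(4)
    }
    asn, meta = _composition_inputs(layout)
    fractions, tests = compartment_composition(asn, meta, paired=True)
    assert np.allclose(fractions.sum(axis=1), 1.0, atol=1e-12)
    for _, row in tests.iterrows():
        assert row["t"] == 0.0
        assert row["p"] == 1.0


def test_paired_t_matches_closed_form():
    layout = {
        "P1": {"PB": {"c1": 2, "c2": 8}, "SF": {"c1": 5, "c2": 5}},
        "P2": {"PB": {"c1": 3, "c2": 7}, "SF": {"c1": 6, "c2": 4}},
        "P3": {"PB": {"c1": 1, "c2": 9}, "SF": {"c1": 7, "c2": 3}},
        "P4": {"PB": {"c1": 4, "c2": 6}, "SF": {"c1": 8, "c2": 2}},
    }
    asn, meta = _composition_inputs(layout)
    _, tests = compartment_composition(asn, meta, paired=True)
    pb = np.array([0.2, 0.3, 0.1, 0.4])
    sf = np.array([0.5, 0.6, 0.7, 0.8])
    d = sf - pb
    t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p_expected = 2 * st.t.sf(abs(t_expected), len(d) - 1)
    row = tests[tests["cluster"] == "c1"].iloc[0]
    assert abs(row["t"]) == pytest.approx(abs(t_expected), rel=1e-10)
    assert row["p"] == pytest.approx(p_expected, rel=1e-10)


def test_paired_with_unmatched_patients_errors():
    layout = {
        "P1": {"PB": {"c1": 5, "c2": 5}, "SF": {"c1": 5, "c2": 5}},
        "P2": {"PB": {"c1": 5, "c2": 5}},
    }
    asn, meta = _composition_inputs(layout)
    with pytest.raises(SynocloneError, match="P2"):
        compartment_composition(asn, meta, paired=True)
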