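"""Clonotype calling, expansion ranking, and repertoire-overlap testing.

A clonotype is the exact set of productive (chain, V gene, J gene,
CDR3 nucleotide) tuples carried by a cell; cells with identical
signatures belong to one clone.  Cluster-pair repertoire overlap is
tested with a one-sided (enrichment) Fisher exact test over the clone
universe, followed by Benjamini-Hochberg FDR adjustment — the statistic
behind the shared-clonotype heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClusterAssignment, SynocloneError, validate_contigs
from .stats import bh_adjust, fisher_enrichment_p


@dataclass
class ClonotypeTable:
    """Clones with member cells.

    ``clones``: one row per clone (clone_id, signature, n_cells).
    ``cell_to_clone``: barcode -> clone_id for every clone-bearing cell.
    """

    clones: pd.DataFrame
    cell_to_clone: pd.Series

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def members(self, clone_id: str) -> list[str]:
        return list(self.cell_to_clone.index[self.cell_to_clone == clone_id])


def call_clonotypes(contigs: pd.DataFrame) -> ClonotypeTable:
    """Group cells into clones by exact productive-chain signature.

    Nonproductive contigs are discarded; chains other than TRA/TRB do not
    enter the signature.  Cells carrying more than one TRA or TRB keep
    all productive chains in the signature, so multi-chain cells form
    their own clones unless signatures match exactly.  Cells with no
    productive TRA/TRB chain are absent from the table.
    """
    df = validate_contigs(contigs) if "non_abg" not in contigs.columns else contigs
    df = df[df["productive"] & df["chain"].isin(["TRA", "TRB"])]
    if df.empty:
        return ClonotypeTable(
            clones=pd.DataFrame(columns=["clone_id", "signature", "n_cells"]),
            cell_to_clone=pd.Series(dtype=object, name="clone_id"),
        )
    sig_per_cell = (
        df.assign(
            chain_sig=df["chain"] + "|" + df["v_gene"] + "|" + df["j_gene"] + "|" + df["cdr3_nt"]
        )
        .groupby("barcode")["chain_sig"]
        .apply(lambda s: ";".join(sorted(set(s))))
    )
    signatures = sorted(sig_per_cell.unique())
    clone_ids = {sig: f"clone_{i+1:05d}" for i, sig in enumerate(signatures)}
    cell_to_clone = sig_per_cell.map(clone_ids).rename("clone_id")
    clones = (
        cell_to_clone.value_counts()
        .rename("n_cells")
        .rename_axis("clone_id")
        .reset_index()
        .merge(
            pd.DataFrame(
                {"clone_id": list(clone_ids.values()), "signature": list(clone_ids.keys())}
            ),
            on="clone_id",
        )
        .sort_values("clone_id")
        .reset_index(drop=True)[["clone_id", "signature", "n_cells"]]
    )
    return ClonotypeTable(clones=clones, cell_to_clone=cell_to_clone)


def clonal_fraction(
    clonotypes: ClonotypeTable, cell_meta: pd.DataFrame, sample_id: str
) -> pd.Series:
    """Per-clone fraction of a sample's clone-bearing cells.

    Fractions sum to 1 over the clones present in the sample.
    """
    meta = cell_meta.reindex(clonotypes.cell_to_clone.index)
    in_sample = clonotypes.cell_to_clone[meta["sample_id"] == sample_id]
    if in_sample.empty:
        raise SynocloneError(f"sample has no clone-bearing cells: {sample_id}")
    counts = in_sample.value_counts()
    return counts / counts.sum()


def top_expanded(
    clonotypes: ClonotypeTable,
    assignment: ClusterAssignment,
    cell_meta: pd.DataFrame | None = None,
    n: int = 100,
    scope: str = "per_compartment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-n expanded clones and their clone x cluster cell-count matrix.

    Clones are ranked by cell count within each scope group (compartment
    or sample), descending; ties break by total cells across the dataset
    (larger first), then lexicographic clone id.
    """
    if n <= 0:
        raise SynocloneError("n must be positive")
    if scope not in {"per_compartment", "per_sample"}:
        raise SynocloneError(f"unknown scope: {scope}")
    cells = clonotypes.cell_to_clone.to_frame()
    if cell_meta is None:
        cells["group"] = "all"
    else:
        meta = cell_meta.reindex(cells.index)
        cells["group"] = (
            meta["compartment"] if scope == "per_compartment" else meta["sample_id"]
        )
    totals = clonotypes.cell_to_clone.value_counts()

    ranked_rows = []
    for group, sub in cells.groupby("group"):
        counts = sub["clone_id"].value_counts()
        order = sorted(
            counts.index, key=lambda cid: (-counts[cid], -totals[cid], cid)
        )
        for rank, cid in enumerate(order[:n], start=1):
            ranked_rows.append(
                {
                    "group": group,
                    "rank": rank,
                    "clone_id": cid,
                    "n_cells_in_group": int(counts[cid]),
                    "n_cells_total": int(totals[cid]),
                }
            )
    ranked = pd.DataFrame(ranked_rows)

    labels = assignment.labels.reindex(cells.index)
    top_ids = sorted(set(ranked["clone_id"])) if not ranked.empty else []
    mat = (
        pd.crosstab(clonotypes.cell_to_clone, labels)
        .reindex(top_ids)
        .fillna(0)
        .astype(int)
    )
    mat.index.name = "clone_id"
    return ranked, mat


def clone_cluster_membership(
    clonotypes: ClonotypeTable, assignment: ClusterAssignment, min_cells: int = 1
) -> dict[str, set[str]]:
    """cluster label -> set of clone ids with >= min_cells member cells there."""
    labels = assignment.labels.reindex(clonotypes.cell_to_clone.index)
    df = pd.DataFrame({"clone_id": clonotypes.cell_to_clone, "cluster": labels}).dropna()
    counts = df.groupby(["cluster", "clone_id"]).size()
    out: dict[str, set[str]] = {}
    for (cluster, clone_id), k in counts.items():
        if k >= min_cells:
            out.setdefault(str(cluster), set()).add(clone_id)
    return out


def overlap_matrix(
    clonotypes: ClonotypeTable | dict[str, set[str]],
    assignment: ClusterAssignment | None = None,
) -> pd.DataFrame:
    """Symmetric shared-clone count matrix across clusters.

    Entry (i, j), i != j, counts clones with >= 1 cell in both clusters;
    the diagonal counts clones present in the cluster.  Accepts either a
    clonotype table plus assignment, or a precomputed
    cluster -> clone-set membership map.
    """
    if isinstance(clonotypes, dict):
        membership = clonotypes
    else:
        if assignment is None:
            raise SynocloneError("assignment required with a ClonotypeTable")
        membership = clone_cluster_membership(clonotypes, assignment)
    names = sorted(membership)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        mat.loc[a, a] = len(membership[a])
        for b in names[i + 1 :]:
            shared = len(membership[a] & membership[b])
            mat.loc[a, b] = shared
            mat.loc[b, a] = shared
    return mat


def overlap_test(
    overlap: pd.DataFrame,
    universe_size: int,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment test per unordered cluster pair + BH.

    The 2x2 table for a pair (A, B) over the clone universe is
    [[shared, A-only], [B-only, universe - A-union-B]]; the one-sided
    enrichment p is the hypergeometric upper tail.  Pairs where either
    side has zero clones are not tested.
    """
    names = list(overlap.index)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            n_a = int(overlap.loc[a, a])
            n_b = int(overlap.loc[b, b])
            if n_a == 0 or n_b == 0:
                continue
            shared = int(overlap.loc[a, b])
            p = fisher_enrichment_p(shared, n_a, n_b, universe_size)
            rows.append(
                {
                    "cluster_a": a,
                    "cluster_b": b,
                    "n_shared": shared,
                    "n_clones_a": n_a,
                    "n_clones_b": n_b,
                    "universe_size": universe_size,
                    "p_one_sided": p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_bh"] = []
        out["significant"] = []
        return out
    out["q_bh"] = bh_adjust(out["p_one_sided"].to_numpy())
    out["significant"] = out["q_bh"] < q_threshold
    return out


def universe_size_of(clonotypes: ClonotypeTable | dict[str, set[str]]) -> int:
    """Total distinct clonotypes in the dataset (the Fisher universe)."""
    if isinstance(clonotypes, dict):
        all_ids: set[str] = set()
        for ids in clonotypes.values():
            all_ids |= ids
        return len(all_ids)
    return clonotypes.n_clones
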