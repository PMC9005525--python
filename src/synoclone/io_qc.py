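"""Reading the 10x-convention inputs and cell-level quality control.

Filtering follows the study's printed rules with strict inequalities:
cells aligned to <200 genes (low-complexity debris), >15% mitochondrial
transcripts (dying cells), and >6500 genes (suspected multiplets) are
removed; boundary values are retained.  Doublet flagging is the multi-step
union: library complexity, hybrid lineage-marker expression, wholesale
hybrid clusters, and an optional precomputed external doublet score.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CONTIG_COLUMNS,
    CellGeneMatrix,
    ClusterAssignment,
    SynocloneError,
    validate_contigs,
)


@dataclass
class QCThresholds:
    """Cell-filtering cut-offs (strict inequalities; boundaries retained)."""

    min_genes: int = 200
    max_genes: int = 6500
    max_pct_mito: float = 15.0
    mito_prefix: str = "MT-"
    external_doublet_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise SynocloneError("min_genes must be < max_genes")
        if not 0.0 < self.max_pct_mito < 100.0:
            raise SynocloneError("max_pct_mito must lie in (0, 100)")


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_mito: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def _open_maybe_gz(path_plain: str):
    """Return an open binary handle for path or path.gz, else None."""
    if os.path.exists(path_plain):
        return open(path_plain, "rb"), path_plain
    gz = path_plain + ".gz"
    if os.path.exists(gz):
        return gzip.open(gz, "rb"), gz
    return None, path_plain


def read_matrix(dir_path: str) -> CellGeneMatrix:
    """Read matrix.mtx / barcodes.tsv / features.tsv (optionally gzipped)
    plus optional metadata.tsv from a directory."""
    fh, mtx_path = _open_maybe_gz(os.path.join(dir_path, "matrix.mtx"))
    if fh is None:
        raise SynocloneError(f"matrix.mtx not found in {dir_path}")
    with fh:
        counts = sp.csr_matrix(scipy.io.mmread(fh))

    def read_lines(name: str) -> list[list[str]]:
        handle, path = _open_maybe_gz(os.path.join(dir_path, name))
        if handle is None:
            raise SynocloneError(f"{name} not found in {dir_path}")
        with handle:
            text = handle.read().decode()
        return [line.split("\t") for line in text.splitlines() if line], path

    bc_rows, bc_path = read_lines("barcodes.tsv")
    ft_rows, ft_path = read_lines("features.tsv")
    barcodes = [r[0] for r in bc_rows]
    if len(barcodes) != counts.shape[1]:
        raise SynocloneError(
            f"{bc_path}: {len(barcodes)} barcodes but matrix declares "
            f"{counts.shape[1]} columns"
        )
    if len(ft_rows) != counts.shape[0]:
        raise SynocloneError(
            f"{ft_path}: {len(ft_rows)} features but matrix declares "
            f"{counts.shape[0]} rows"
        )
    gene_ids = [r[0] for r in ft_rows]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in ft_rows]

    meta_path = os.path.join(dir_path, "metadata.tsv")
    meta = None
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
    return CellGeneMatrix(counts, gene_ids, gene_symbols, barcodes, meta)


def read_contigs(path: str) -> pd.DataFrame:
    """Read a V(D)J contig table (TSV or CSV).  Chains other than TRA/TRB
    are retained but flagged in the ``non_abg`` column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"cdr3_nt": str, "cdr3_aa": str})
    for col in ("cdr3_nt", "cdr3_aa"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return validate_contigs(df)


def compute_cell_qc(matrix: CellGeneMatrix, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC quantities: genes_detected, total_umis, percent_mito.

    percent_mito = 100 * mito UMIs / total UMIs, defined as 0 for empty
    cells; mitochondrial genes are matched by symbol prefix,
    case-insensitively.
    """
    thresholds = thresholds or QCThresholds()
    csc = matrix.counts.tocsc()
    genes_detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    total = np.asarray(csc.sum(axis=0)).ravel()
    prefix = thresholds.mito_prefix.upper()
    mito_rows = [i for i, s in enumerate(matrix.gene_symbols) if s.upper().startswith(prefix)]
    mito = (
        np.asarray(csc[mito_rows, :].sum(axis=0)).ravel()
        if mito_rows
        else np.zeros_like(total)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_umis": total.astype(int),
            "percent_mito": pct,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def apply_qc_filters(
    matrix: CellGeneMatrix,
    qc_table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CellGeneMatrix, FilterReport]:
    """Remove cells failing any rule (union semantics); strict boundaries."""
    thresholds = thresholds or QCThresholds()
    missing = set(matrix.barcodes) - set(qc_table.index)
    if missing:
        raise SynocloneError(f"qc_table missing barcodes, e.g. {sorted(missing)[:3]}")
    qc = qc_table.loc[matrix.barcodes]
    low = qc["genes_detected"] < thresholds.min_genes
    high = qc["genes_detected"] > thresholds.max_genes
    mito = qc["percent_mito"] > thresholds.max_pct_mito
    fail = low | high | mito
    keep = [b for b, f in zip(matrix.barcodes, fail) if not f]
    report = FilterReport(
        n_input=matrix.n_cells,
        n_removed=int(fail.sum()),
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_mito=int(mito.sum()),
    )
    return matrix.subset_cells(keep), report


def flag_doublets(
    matrix: CellGeneMatrix,
    clusters: ClusterAssignment | pd.Series,
    lineage_marker_sets: dict[str, list[str]],
    cluster_lineages: dict[str, str] | None = None,
    external_scores: pd.Series | None = None,
    k_offlineage: int = 2,
    max_genes: int = 6500,
    external_cutoff: float | None = None,
    hybrid_cluster_mean: float = 2.0,
    max_iter: int = 5,
) -> pd.DataFrame:
    """Multi-step doublet flagging; union of flags = doublet call.

    Flags per cell: ``high_complexity`` (genes_detected > max_genes),
    ``hybrid_marker`` (>= k_offlineage genes of a lineage set other than
    the cell's cluster lineage detected at UMI > 0), ``hybrid_cluster``
    (whole cluster whose mean per-cell detected-marker count reaches
    ``hybrid_cluster_mean`` for >= 2 lineage sets), and ``external``
    (precomputed score > cutoff).  When ``cluster_lineages`` is not given
    each cluster's lineage is inferred as the marker set with the highest
    mean detected-gene count.  The flag/remove cycle is iterated until no
    new flags appear (lineage inference can shift once doublets leave).
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    labels = labels.reindex(matrix.barcodes)
    if labels.isna().any():
        raise SynocloneError("cluster assignment does not cover all barcodes")

    set_names = sorted(lineage_marker_sets)
    row_sets = {}
    for name in set_names:
        rows = [i for i, s in enumerate(matrix.gene_symbols) if s in set(lineage_marker_sets[name])]
        row_sets[name] = rows
    csc = matrix.counts.tocsc()
    detected = csc > 0
    # cells x lineage-sets matrix of detected marker counts
    marker_counts = np.column_stack(
        [
            np.asarray(detected[rows, :].sum(axis=0)).ravel()
            if rows
            else np.zeros(matrix.n_cells)
            for rows in (row_sets[n] for n in set_names)
        ]
    )
    genes_detected = np.asarray(detected.sum(axis=0)).ravel()

    cluster_names = sorted(labels.unique())
    if cluster_lineages is not None:
        unassigned = [c for c in cluster_names if c not in cluster_lineages]
        if unassigned:
            raise SynocloneError(f"clusters without a lineage assignment: {unassigned}")

    label_arr = labels.to_numpy()
    flags = pd.DataFrame(
        False,
        index=pd.Index(matrix.barcodes, name="barcode"),
        columns=["high_complexity", "hybrid_marker", "hybrid_cluster", "external"],
    )
    flags["high_complexity"] = genes_detected > max_genes
    if external_scores is not None and (external_cutoff is not None):
        ext = external_scores.reindex(matrix.barcodes).fillna(-np.inf)
        flags["external"] = (ext > external_cutoff).to_numpy()

    active = np.ones(matrix.n_cells, dtype=bool)
    for _ in range(max_iter):
        new_flags = np.zeros(matrix.n_cells, dtype=bool)
        # lineage of each cluster, from unflagged cells only
        lineage_of: dict[str, str] = {}
        for c in cluster_names:
            in_c = (label_arr == c) & active
            if cluster_lineages is not None:
                lineage_of[c] = cluster_lineages[c]
            elif in_c.any():
                means = marker_counts[in_c].mean(axis=0)
                lineage_of[c] = set_names[int(np.argmax(means))]
            else:
                lineage_of[c] = set_names[0]
        # hybrid cluster: >= 2 lineage sets with high mean detected markers
        for c in cluster_names:
            in_c = (label_arr == c) & active
            if not in_c.any():
                continue
            means = marker_counts[in_c].mean(axis=0)
            if int((means >= hybrid_cluster_mean).sum()) >= 2:
                flags.loc[in_c, "hybrid_cluster"] = True
                new_flags |= in_c
        # hybrid marker: off-lineage markers detected in an individual cell
        for j, name in enumerate(set_names):
            off = np.array([lineage_of[c] != name for c in label_arr])
            hit = off & (marker_counts[:, j] >= k_offlineage) & active
            if hit.any():
                flags.loc[hit, "hybrid_marker"] = True
                new_flags |= hit
        union = flags.any(axis=1).to_numpy()
        newly_flagged = active & union
        if not newly_flagged.any():
            break
        active &= ~union
    flags["is_doublet"] = flags.any(axis=1)
    return flags


def write_filter_report(report: FilterReport, path: str) -> None:
    pd.DataFrame([report.__dict__ | {"n_retained": report.n_retained}]).to_csv(
        path, sep="\t", index=False
    )
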