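"""Core in-memory containers shared across the pipeline.

The substrate of every analysis stage is a sparse genes x cells raw UMI
count matrix with per-barcode metadata (patient, compartment PB/SF,
sample), plus per-cell V(D)J contig records.  Containers are deliberately
thin: sparse matrices from scipy, tables from pandas, with invariant
checks at construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: required columns of a contig table (one row per assembled V(D)J contig)
CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3_nt",
    "cdr3_aa",
    "productive",
    "umis",
]

#: metadata columns attached to each cell barcode
META_COLUMNS = ["patient", "compartment", "sample_id"]


class SynocloneError(ValueError):
    """Base class for contract violations raised by this package."""


@dataclass
class CellGeneMatrix:
    """Raw UMI counts (genes x cells) with aligned labels and metadata.

    Parameters
    ----------
    counts
        Sparse nonnegative integer matrix, genes in rows, cells in columns.
    gene_ids, gene_symbols
        Per-row identifiers; symbols are what marker logic matches on.
    barcodes
        Per-column cell barcodes, unique within a dataset.
    cell_meta
        DataFrame indexed by barcode with columns patient, compartment
        (PB or SF), sample_id.  Missing metadata is filled with "unknown".
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise SynocloneError(
                f"gene label length mismatch: matrix has {n_genes} rows, "
                f"{len(self.gene_ids)} gene_ids / {len(self.gene_symbols)} symbols"
            )
        if len(self.barcodes) != n_cells:
            raise SynocloneError(
                f"barcode length mismatch: matrix has {n_cells} columns, "
                f"{len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise SynocloneError("duplicate barcodes in matrix")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise SynocloneError("negative counts are not allowed")
        meta = self.cell_meta
        if meta is None:
            meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        meta = meta.reindex(self.barcodes)
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = "unknown"
            meta[col] = meta[col].fillna("unknown")
        meta.index.name = "barcode"
        self.cell_meta = meta[META_COLUMNS + [c for c in meta.columns if c not in META_COLUMNS]]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbol: str) -> int:
        """Row index of a gene symbol; raises if absent."""
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise SynocloneError(f"gene symbol not in matrix: {symbol}") from None

    def subset_cells(self, keep: Sequence[str]) -> "CellGeneMatrix":
        """Return a new matrix restricted to (and ordered by) ``keep``."""
        pos = {b: i for i, b in enumerate(self.barcodes)}
        missing = [b for b in keep if b not in pos]
        if missing:
            raise SynocloneError(f"barcodes not in matrix: {missing[:5]}")
        idx = [pos[b] for b in keep]
        return CellGeneMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=list(keep),
            cell_meta=self.cell_meta.loc[list(keep)].copy(),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, same layout as :class:`CellGeneMatrix`.

    Values are log2(count / cell_total * scale + 1); the unit every
    downstream threshold (marker detection, ligand-receptor calls) is
    defined in.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame
    scale: float = 10_000.0
    base: float = 2.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise SynocloneError(f"gene symbol not in matrix: {symbol}") from None

    def subset_cells(self, keep: Sequence[str]) -> "NormalizedMatrix":
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in keep]
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=list(keep),
            cell_meta=self.cell_meta.loc[list(keep)].copy(),
            scale=self.scale,
            base=self.base,
        )


@dataclass
class ClusterAssignment:
    """Barcode -> cluster label for one clustering round."""

    labels: pd.Series  # index barcode, values str labels
    round_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index.name = "barcode"
        if self.labels.index.has_duplicates:
            raise SynocloneError("duplicate barcodes in cluster assignment")

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.labels.unique())

    def barcodes_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside a synthetic dataset.

    ``cell_cluster`` maps every emitted barcode (doublets included; a
    doublet inherits its first parent's label) to the generating cluster.
    ``shared_clone_ids`` maps a cluster pair (sorted tuple) to the clone
    ids planted in both members.  ``planted_lr`` holds
    (ligand, receptor, sender_cluster, receiver_cluster) tuples that a
    caller at the >20% threshold must recover.
    """

    cell_cluster: dict[str, str]
    doublet_barcodes: set[str]
    shared_clone_ids: dict[tuple[str, str], set[str]]
    planted_lr: set[tuple[str, str, str, str]]
    seed: int

    def to_json(self) -> str:
        payload = {
            "cell_cluster": self.cell_cluster,
            "doublet_barcodes": sorted(self.doublet_barcodes),
            "shared_clone_ids": {
                "|".join(pair): sorted(ids) for pair, ids in self.shared_clone_ids.items()
            },
            "planted_lr": sorted(list(t) for t in self.planted_lr),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        payload = json.loads(text)
        return cls(
            cell_cluster=dict(payload["cell_cluster"]),
            doublet_barcodes=set(payload["doublet_barcodes"]),
            shared_clone_ids={
                tuple(k.split("|")): set(v)
                for k, v in payload["shared_clone_ids"].items()
            },
            planted_lr={tuple(t) for t in payload["planted_lr"]},
            seed=int(payload["seed"]),
        )


def validate_contigs(df: pd.DataFrame) -> pd.DataFrame:
    """Check required contig columns and coerce types in place."""
    for col in CONTIG_COLUMNS:
        if col not in df.columns:
            raise SynocloneError(f"contig table missing required column: {col}")
    out = df.copy()
    if out["productive"].dtype != bool:
        out["productive"] = (
            out["productive"].astype(str).str.strip().str.lower().isin(["true", "t", "1"])
        )
    out["umis"] = out["umis"].astype(int)
    bad = out["productive"] & (out["cdr3_nt"].astype(str).str.len() == 0)
    if bad.any():
        raise SynocloneError("productive contig with empty cdr3_nt")
    out["non_abg"] = ~out["chain"].isin(["TRA", "TRB"])
    return out


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying numpy/pandas payloads."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
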