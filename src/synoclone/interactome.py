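"""Ligand-receptor interaction calling between cell clusters.

A gene is "expressed" in a cluster when strictly more than 20% of its
cells have log2(normalized UMI + 1) > 0.  A call (L, R, sender ->
receiver) is emitted when the ligand is expressed in the sender and the
paired receptor in the receiver; both directions and self-pairs are
evaluated.  Each call carries a surrogate score — the product of the
mean log-normalized ligand and receptor expression — which preserves the
"higher expression, thicker edge" semantics and vanishes when either
side is silent.  The differential interactome annotates pairs whose
ligand and/or receptor is a significant cluster marker.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import ClusterAssignment, NormalizedMatrix, SynocloneError

logger = logging.getLogger(__name__)

LR_COLUMNS = ["ligand_gene", "receptor_gene", "category"]


def load_lr_pairs(path: str | None = None) -> pd.DataFrame:
    """Load a curated ligand-receptor pair list (TSV).

    With no path, the bundled minimal chemokine demo list is returned
    (CXCL9/10/11 -> CXCR3, CXCL16 -> CXCR6, CX3CL1 -> CX3CR1, CCL5 -> CCR5).
    """
    if path is None:
        ref = resources.files("synoclone.data").joinpath("lr_pairs_demo.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in LR_COLUMNS[:2]:
        if col not in df.columns:
            raise SynocloneError(f"LR pair list missing column: {col}")
    if "category" not in df.columns:
        df["category"] = "unknown"
    if df.duplicated(subset=["ligand_gene", "receptor_gene"]).any():
        raise SynocloneError("duplicate ligand-receptor pairs in list")
    return df[LR_COLUMNS]


def expressed_genes(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    frac_threshold: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Per cluster: every gene's positive-cell fraction and mean expression.

    The ``expressed`` column is True iff the fraction of cells with
    value > 0 strictly exceeds ``frac_threshold``.
    """
    labels = assignment.labels.reindex(norm.barcodes)
    if labels.isna().any():
        raise SynocloneError("assignment does not cover all cells in the matrix")
    dense = np.asarray(norm.values.todense())
    out: dict[str, pd.DataFrame] = {}
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).to_numpy()
        block = dense[:, mask]
        frac = (block > 0).mean(axis=1)
        out[str(cluster)] = pd.DataFrame(
            {
                "gene": norm.gene_symbols,
                "frac_positive": frac,
                "mean_expression": block.mean(axis=1),
                "expressed": frac > frac_threshold,
            }
        ).set_index("gene")
    return out


def match_lr_pairs(
    expressed: dict[str, pd.DataFrame],
    lr_list: pd.DataFrame,
    senders: list[str] | None = None,
    receivers: list[str] | None = None,
) -> pd.DataFrame:
    """Emit calls (L, R, sender -> receiver) where the ligand is expressed
    in the sender and the receptor in the receiver.

    Cluster roles can be restricted (e.g. myeloid senders, T receivers);
    genes absent from the matrix universe are skipped with a warning.
    """
    clusters = sorted(expressed)
    for role, subset in (("sender", senders), ("receiver", receivers)):
        if subset is not None:
            unknown = set(subset) - set(clusters)
            if unknown:
                raise SynocloneError(f"unknown {role} clusters: {sorted(unknown)}")
    senders = senders if senders is not None else clusters
    receivers = receivers if receivers is not None else clusters
    universe = set(next(iter(expressed.values())).index) if expressed else set()
    rows = []
    for _, pair in lr_list.iterrows():
        lig, rec = pair["ligand_gene"], pair["receptor_gene"]
        if lig not in universe or rec not in universe:
            logger.warning("LR pair gene absent from matrix: %s -> %s", lig, rec)
            continue
        for s in senders:
            if not expressed[s].loc[lig, "expressed"]:
                continue
            for r in receivers:
                if not expressed[r].loc[rec, "expressed"]:
                    continue
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender_cluster": s,
                        "receiver_cluster": r,
                        "category": pair.get("category", "unknown"),
                        "frac_ligand": float(expressed[s].loc[lig, "frac_positive"]),
                        "frac_receptor": float(expressed[r].loc[rec, "frac_positive"]),
                        "mean_ligand": float(expressed[s].loc[lig, "mean_expression"]),
                        "mean_receptor": float(expressed[r].loc[rec, "mean_expression"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand",
            "receptor",
            "sender_cluster",
            "receiver_cluster",
            "category",
            "frac_ligand",
            "frac_receptor",
            "mean_ligand",
            "mean_receptor",
        ],
    )


def score_interactions(calls: pd.DataFrame) -> pd.DataFrame:
    """Attach score = mean_ligand * mean_receptor; sort descending.

    A surrogate magnitude, not a statistical quantity: zero iff either
    side's mean expression is zero.
    """
    out = calls.copy()
    out["score"] = out["mean_ligand"] * out["mean_receptor"]
    return out.sort_values(
        ["score", "ligand", "receptor", "sender_cluster", "receiver_cluster"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)


def differential_interactome(
    markers: pd.DataFrame,
    lr_list: pd.DataFrame,
    q_max: float = 0.05,
    min_frac: float = 0.2,
) -> pd.DataFrame:
    """LR pairs whose ligand and/or receptor is a significant DEG.

    ``markers`` is a marker table computed with min detection fraction
    ``min_frac`` (kept as an explicit parameter to document the
    contract); each emitted row names the differential side(s) and the
    corresponding log2 fold change and cluster.
    """
    sig = markers[(markers["q_value"] < q_max) & (markers["pct_in"] >= min_frac)]
    by_gene: dict[str, pd.DataFrame] = {g: sub for g, sub in sig.groupby("gene")}
    rows = []
    for _, pair in lr_list.iterrows():
        lig, rec = pair["ligand_gene"], pair["receptor_gene"]
        lig_hits = by_gene.get(lig)
        rec_hits = by_gene.get(rec)
        if lig_hits is None and rec_hits is None:
            continue
        side = (
            "both"
            if lig_hits is not None and rec_hits is not None
            else ("ligand" if lig_hits is not None else "receptor")
        )
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "differential_side": side,
                "ligand_clusters": (
                    ";".join(sorted(lig_hits["cluster"].astype(str))) if lig_hits is not None else ""
                ),
                "receptor_clusters": (
                    ";".join(sorted(rec_hits["cluster"].astype(str))) if rec_hits is not None else ""
                ),
                "max_abs_log2_fc": float(
                    pd.concat(
                        [h["log2_fc"] for h in (lig_hits, rec_hits) if h is not None]
                    )
                    .abs()
                    .max()
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand",
            "receptor",
            "differential_side",
            "ligand_clusters",
            "receptor_clusters",
            "max_abs_log2_fc",
        ],
    )
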