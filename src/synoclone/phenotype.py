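"""Normalization, graph clustering, marker detection and annotation.

The clustering pipeline mirrors the standard single-cell workflow:
top-2000 highly variable genes, per-gene scaling (clipped at +/-10), PCA,
a k-nearest-neighbor graph turned into a shared-nearest-neighbor (SNN)
graph with Jaccard edge weights, and seeded modularity community
detection (Leiden) at a resolution parameter.  The three configured
rounds reproduce the analysis design: a major round (40 PCs, 200
neighbors, resolution 0.6), an NK/NKT/T subclustering round (30, 30,
0.8), and a Treg subclustering round (30, 30, 0.1).

Cell order is canonicalized (barcode-sorted) before clustering and
cluster labels are renamed by decreasing size, so the partition is
invariant to the order cells arrive in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import (
    CellGeneMatrix,
    ClusterAssignment,
    NormalizedMatrix,
    SynocloneError,
)
from .stats import anova_bonferroni, bh_adjust, paired_t, ranksum_test

logger = logging.getLogger(__name__)


@dataclass
class ClusteringParams:
    """Parameters of one clustering round."""

    n_hvg: int = 2000
    n_pcs: int = 40
    k_neighbors: int = 200
    resolution: float = 0.6
    seed: int = 0
    round_id: str = "major"

    def __post_init__(self) -> None:
        if self.n_pcs > self.n_hvg:
            raise SynocloneError("n_pcs must be <= n_hvg")
        if self.resolution <= 0:
            raise SynocloneError("resolution must be positive")


#: the three configured rounds (PCs, neighbors, resolution)
ROUND_DEFAULTS: dict[str, ClusteringParams] = {
    "major": ClusteringParams(n_pcs=40, k_neighbors=200, resolution=0.6, round_id="major"),
    "nk_t_sub": ClusteringParams(n_pcs=30, k_neighbors=30, resolution=0.8, round_id="nk_t_sub"),
    "treg_sub": ClusteringParams(n_pcs=30, k_neighbors=30, resolution=0.1, round_id="treg_sub"),
}


@dataclass
class MarkerRule:
    """Declarative annotation rule: a cluster earns ``label`` when all
    ``required`` genes are among its significant markers and no
    ``forbidden`` gene is."""

    label: str
    required: list[str]
    forbidden: list[str] = field(default_factory=list)
    min_log2_fc: float = 0.25

    def __post_init__(self) -> None:
        if set(self.required) & set(self.forbidden):
            raise SynocloneError(f"rule {self.label}: required and forbidden overlap")


def normalize_log(matrix: CellGeneMatrix, scale: float = 10_000.0, base: float = 2.0) -> NormalizedMatrix:
    """Library-size normalization then log: x -> log_base(x / total * scale + 1).

    Zero cells map to zeros.  Base 2 keeps every downstream threshold in
    the log2(normalized UMI + 1) unit.
    """
    csc = matrix.counts.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    inv = np.where(totals > 0, scale / np.maximum(totals, 1.0), 0.0)
    csc = csc @ sp.diags(inv)
    csc.data = np.log1p(csc.data) / np.log(base)
    return NormalizedMatrix(
        values=csc.tocsr(),
        gene_ids=list(matrix.gene_ids),
        gene_symbols=list(matrix.gene_symbols),
        barcodes=list(matrix.barcodes),
        cell_meta=matrix.cell_meta.copy(),
        scale=scale,
        base=base,
    )


def select_hvg(norm: NormalizedMatrix, n_hvg: int) -> np.ndarray:
    """Indices of the top-n highly variable genes.

    Ranking is by variance of the log-normalized expression (a
    standardized-variance/dispersion ranking); ties break by gene order
    for determinism.
    """
    csc = norm.values.tocsc()
    n = norm.n_cells
    mean = np.asarray(csc.mean(axis=1)).ravel()
    sq = np.asarray(csc.multiply(csc).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    order = np.lexsort((np.arange(len(var)), -var))
    return np.sort(order[: min(n_hvg, len(var))])


def _snn_graph(pcs: np.ndarray, k: int, prune: float = 1 / 15) -> ig.Graph:
    """SNN graph with Jaccard weights from the kNN graph on PC space."""
    n = pcs.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, algorithm="brute").fit(pcs)
    _, idx = nn.kneighbors(pcs)
    # neighbor sets include the cell itself (column 0)
    rows = np.repeat(np.arange(n), k_eff + 1)
    cols = idx.ravel()
    adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    shared = (adj @ adj.T).tocoo()
    ksz = k_eff + 1
    jac = shared.data / (2 * ksz - shared.data)
    mask = (shared.row < shared.col) & (jac > prune)
    edges = list(zip(shared.row[mask].tolist(), shared.col[mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[mask].tolist()
    return g


def cluster_cells(norm: NormalizedMatrix, params: ClusteringParams) -> ClusterAssignment:
    """HVG -> scale(clip 10) -> PCA -> kNN -> SNN(Jaccard) -> Leiden.

    Deterministic at a fixed seed and invariant to input cell order.
    """
    n_cells = norm.n_cells
    if n_cells < 3:
        raise SynocloneError("need at least 3 cells to cluster")
    # canonical cell order
    order = np.argsort(np.array(norm.barcodes))
    barcodes_sorted = [norm.barcodes[i] for i in order]
    values = norm.values.tocsc()[:, order]

    hvg = select_hvg(norm, params.n_hvg)
    X = np.asarray(values[hvg, :].todense()).T  # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10.0, 10.0)

    n_pcs = min(params.n_pcs, X.shape[1], n_cells - 1)
    if n_pcs < params.n_pcs:
        logger.warning("reducing n_pcs from %d to %d (small input)", params.n_pcs, n_pcs)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pcs = pca.fit_transform(X)
    # sign convention: largest-|loading| coordinate positive
    for j in range(pcs.shape[1]):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            pcs[:, j] *= -1

    g = _snn_graph(pcs, params.k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=params.resolution,
        seed=params.seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    # canonical relabel: decreasing size, ties by first canonical cell
    sizes = pd.Series(raw).value_counts()
    firsts = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    ranked = sorted(sizes.index, key=lambda lab: (-sizes[lab], firsts[lab]))
    relabel = {lab: str(i) for i, lab in enumerate(ranked)}
    labels = pd.Series(
        [relabel[v] for v in raw], index=pd.Index(barcodes_sorted, name="barcode")
    )
    labels = labels.reindex(norm.barcodes)
    return ClusterAssignment(
        labels=labels,
        round_id=params.round_id,
        params={
            "n_hvg": params.n_hvg,
            "n_pcs": params.n_pcs,
            "k_neighbors": params.k_neighbors,
            "resolution": params.resolution,
            "seed": params.seed,
        },
    )


def subcluster(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    parent_labels: list[str],
    params: ClusteringParams,
) -> ClusterAssignment:
    """Re-cluster the cells of ``parent_labels`` only; labels are
    namespaced by the round id (e.g. ``treg_sub:0``)."""
    if not parent_labels:
        raise SynocloneError("parent_labels must be nonempty")
    unknown = set(parent_labels) - set(assignment.labels.unique())
    if unknown:
        raise SynocloneError(f"parent labels not in assignment: {sorted(unknown)}")
    keep = [b for b in norm.barcodes if assignment.labels.get(b) in set(parent_labels)]
    if not keep:
        raise SynocloneError("parent labels select no cells")
    sub = norm.subset_cells(keep)
    res = cluster_cells(sub, params)
    res.labels = params.round_id + ":" + res.labels.astype(str)
    res = ClusterAssignment(labels=res.labels, round_id=params.round_id, params=res.params)
    return res


def find_markers(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    min_frac: float = 0.2,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon rank-sum marker detection.

    A gene is tested for a cluster when it is detected (UMI > 0) in at
    least ``min_frac`` of in-cluster or of out-cluster cells; log2_fc is
    the difference of in/out mean log-normalized expression; q-values
    are BH across all tests.
    """
    labels = assignment.labels.reindex(norm.barcodes)
    clusters = sorted(labels.dropna().unique())
    if len(clusters) < 2:
        raise SynocloneError("need >= 2 clusters for marker detection")
    dense = np.asarray(norm.values.todense())  # genes x cells
    detected = dense > 0
    rows = []
    for c in clusters:
        in_mask = (labels == c).to_numpy()
        if in_mask.sum() < min_cells:
            warnings.warn(f"cluster {c} has <{min_cells} cells; skipped")
            continue
        out_mask = ~in_mask
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, out_mask].mean(axis=1)
        testable = np.where((pct_in >= min_frac) | (pct_out >= min_frac))[0]
        mean_in = dense[:, in_mask].mean(axis=1)
        mean_out = dense[:, out_mask].mean(axis=1)
        for gi in testable:
            p = ranksum_test(dense[gi, in_mask], dense[gi, out_mask])
            rows.append(
                {
                    "gene": norm.gene_symbols[gi],
                    "cluster": c,
                    "log2_fc": mean_in[gi] - mean_out[gi],
                    "pct_in": pct_in[gi],
                    "pct_out": pct_out[gi],
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_value"] = []
        return out
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(
        ["q_value", "log2_fc"], key=lambda s: s if s.name == "q_value" else -s.abs()
    ).reset_index(drop=True)
    return out


def annotate_clusters(
    markers: pd.DataFrame,
    rules: list[MarkerRule],
    q_max: float = 0.05,
) -> dict[str, str]:
    """Assign each cluster the unique matching rule label, else
    "ambiguous" (several rules match) or "unassigned" (none)."""
    names = [r.label for r in rules]
    if len(set(names)) != len(names):
        raise SynocloneError("duplicate rule labels")
    out: dict[str, str] = {}
    for cluster, sub in markers.groupby("cluster"):
        matches = []
        for rule in rules:
            sig = sub[(sub["q_value"] < q_max) & (sub["log2_fc"] >= rule.min_log2_fc)]
            sig_genes = set(sig["gene"])
            if set(rule.required) <= sig_genes and not (set(rule.forbidden) & sig_genes):
                matches.append(rule.label)
        if len(matches) == 1:
            out[str(cluster)] = matches[0]
        elif len(matches) > 1:
            out[str(cluster)] = "ambiguous"
        else:
            out[str(cluster)] = "unassigned"
    return out


def compartment_composition(
    assignment: ClusterAssignment,
    cell_meta: pd.DataFrame,
    paired: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cluster fractions and PB-vs-SF t tests per cluster.

    Fractions are cluster cells / total sample cells (summing to 1 per
    sample).  With ``paired=True`` a two-sided paired t test across
    patients with both compartments; otherwise unpaired.
    """
    meta = cell_meta.loc[assignment.labels.index]
    df = pd.DataFrame(
        {
            "cluster": assignment.labels.to_numpy(),
            "sample_id": meta["sample_id"].to_numpy(),
            "patient": meta["patient"].to_numpy(),
            "compartment": meta["compartment"].to_numpy(),
        }
    )
    counts = df.groupby(["sample_id", "cluster"]).size().unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    sample_info = df.drop_duplicates("sample_id").set_index("sample_id")[
        ["patient", "compartment"]
    ]

    rows = []
    for cluster in fractions.columns:
        frac = fractions[cluster]
        pb = frac[sample_info["compartment"] == "PB"]
        sf = frac[sample_info["compartment"] == "SF"]
        if paired:
            pb_by_pat = pb.groupby(sample_info.loc[pb.index, "patient"]).mean()
            sf_by_pat = sf.groupby(sample_info.loc[sf.index, "patient"]).mean()
            common = sorted(set(pb_by_pat.index) & set(sf_by_pat.index))
            unmatched = sorted(set(pb_by_pat.index) ^ set(sf_by_pat.index))
            if unmatched:
                raise SynocloneError(f"paired test with unmatched patients: {unmatched}")
            t, p = paired_t(pb_by_pat[common].to_numpy(), sf_by_pat[common].to_numpy())
        else:
            import scipy.stats as st

            if len(pb) > 1 and len(sf) > 1:
                res = st.ttest_ind(sf, pb)
                t, p = float(res.statistic), float(res.pvalue)
            else:
                t, p = float("nan"), float("nan")
        rows.append(
            {
                "cluster": cluster,
                "mean_PB": float(pb.mean()) if len(pb) else float("nan"),
                "mean_SF": float(sf.mean()) if len(sf) else float("nan"),
                "sem_PB": float(pb.sem()) if len(pb) > 1 else float("nan"),
                "sem_SF": float(sf.sem()) if len(sf) > 1 else float("nan"),
                "t": t,
                "p": p,
            }
        )
    return fractions, pd.DataFrame(rows)


def load_marker_rules(path: str) -> list[MarkerRule]:
    """Load YAML rules: list of {label, required, forbidden?, min_log2_fc?}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        rules.append(
            MarkerRule(
                label=entry["label"],
                required=list(entry.get("required", [])),
                forbidden=list(entry.get("forbidden", [])),
                min_log2_fc=float(entry.get("min_log2_fc", 0.25)),
            )
        )
    return rules


# convenience re-export: group comparison helpers used on composition data
compare_groups_anova = anova_bonferroni
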