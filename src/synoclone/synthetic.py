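"""Synthetic paired blood / synovial-fluid single-cell datasets.

Emulates the structure the downstream analysis assumes: per-patient paired
PB and SF samples, negative-binomial cluster-structured UMI counts over a
marker-panel-plus-housekeeping gene universe, doublets built as sums of two
parent cells from different clusters, T-cell clonotypes with planted
cross-compartment clone sharing and a nonproductive-contig fraction, and
planted chemokine ligand/receptor expression patterns (myeloid
CXCL9/10/11/16 senders versus T-cell CXCR3/CXCR6 receivers).  Every planted
feature is recorded in a :class:`~synoclone.datatypes.TruthSet` so each
pipeline stage can be scored against ground truth without any download.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; re-running with the same seed reproduces
bit-identical outputs.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CONTIG_COLUMNS, CellGeneMatrix, SynocloneError, TruthSet

# one fixed codon per amino acid so CDR3 nt/aa pairs are consistent and
# stop-free by construction
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_AA = sorted(_CODON)

#: private clones given to a T cluster not covered by any sharing spec
DEFAULT_PRIVATE_CLONES = 50

#: fraction of T cells carrying at least one productive chain; the study's
#: observed coverage was 69.0% of CD3+ T cells
DEFAULT_TCR_COVERAGE = 0.69

MITO_GENES = ["MT-ND1", "MT-CO1", "MT-CO2", "MT-ATP6", "MT-CYB"]


@dataclass
class ClusterSpec:
    """One planted cell population.

    ``n_cells_per_sample`` cells are emitted per patient; each cell lands
    in SF with probability ``compartment_bias`` (else PB).  Signature
    genes are drawn NB(signature_mean, dispersion) inside the cluster and
    NB(background_mean, dispersion) everywhere else.
    """

    cluster_id: str
    n_cells_per_sample: int
    signature_genes: list[str]
    signature_mean: float = 5.0
    background_mean: float = 0.005
    dispersion: float = 2.0
    compartment_bias: float = 0.5
    t_lineage: bool = False

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise SynocloneError(f"{self.cluster_id}: empty signature gene set")
        if self.signature_mean <= self.background_mean:
            raise SynocloneError(
                f"{self.cluster_id}: signature_mean must exceed background_mean"
            )
        if not 0.0 <= self.compartment_bias <= 1.0:
            raise SynocloneError(f"{self.cluster_id}: compartment_bias outside [0, 1]")
        if self.dispersion <= 0:
            raise SynocloneError(f"{self.cluster_id}: dispersion must be positive")


@dataclass
class CloneSharingSpec:
    """Planted clonal structure for one T-cluster pair.

    ``n_shared_clones`` clonotypes receive cells in both clusters;
    each cluster additionally gets ``n_private_clones_per_cluster``
    private clonotypes.  Remaining TCR-covered cells draw a clone with
    geometrically decaying weights (parameter ``expansion_geometric_p``),
    so early (shared) clones are the most expanded.
    """

    cluster_pair: tuple[str, str]
    n_shared_clones: int = 0
    n_private_clones_per_cluster: int = 50
    expansion_geometric_p: float = 0.1
    nonproductive_fraction: float = 0.1
    multi_chain_fraction: float = 0.027

    def __post_init__(self) -> None:
        if self.n_shared_clones < 0:
            raise SynocloneError("n_shared_clones must be >= 0")
        for name in ("expansion_geometric_p", "nonproductive_fraction", "multi_chain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynocloneError(f"{name} outside [0, 1]")


@dataclass
class LRPlant:
    """One planted ligand-receptor expression pattern.

    ``ligand_on_fraction`` of sender cells (and ``receptor_on_fraction``
    of receiver cells) express the gene at UMI >= 1.  A pair is a planted
    positive iff both fractions exceed the caller's 0.20 threshold;
    decoys keep at least one side at or below it.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    ligand_on_fraction: float
    receptor_on_fraction: float
    on_mean_extra: float = 2.0  # "on" cells draw 1 + Poisson(on_mean_extra)

    @property
    def positive(self) -> bool:
        return self.ligand_on_fraction > 0.20 and self.receptor_on_fraction > 0.20


@dataclass
class LRPlantSpec:
    pairs: list[LRPlant] = field(default_factory=list)


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Unique 16-mer droplet barcodes in 10x style (suffix -1)."""
    seen: set[str] = set()
    out: list[str] = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        bc = "".join(bases[rng.integers(0, 4, size=16)]) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _make_clone(rng: np.random.Generator, clone_idx: int, multi_chain: bool) -> dict:
    """One clonotype: paired TRA+TRB (plus an extra TRA when multi-chain)."""
    chains = []
    chain_plan = ["TRA", "TRB"] + (["TRA"] if multi_chain else [])
    for chain in chain_plan:
        n_aa = int(rng.integers(10, 16))
        aa = "C" + "".join(rng.choice(_AA, size=n_aa - 2)) + "F"
        nt = "".join(_CODON[a] for a in aa)
        v = f"{chain}V{int(rng.integers(1, 30))}"
        j = f"{chain}J{int(rng.integers(1, 20))}"
        chains.append({"chain": chain, "v_gene": v, "j_gene": j, "cdr3_nt": nt, "cdr3_aa": aa})
    return {"clone_id": f"C{clone_idx:05d}", "chains": chains}


def _validate_specs(cluster_specs, sharing_specs, lr_spec) -> None:
    ids = [c.cluster_id for c in cluster_specs]
    if len(set(ids)) != len(ids):
        raise SynocloneError("duplicate cluster_id in cluster_specs")
    seen_genes: dict[str, str] = {}
    for c in cluster_specs:
        for g in c.signature_genes:
            if g in seen_genes:
                raise SynocloneError(
                    f"signature gene {g} appears in both {seen_genes[g]} and {c.cluster_id}"
                )
            seen_genes[g] = c.cluster_id
    known = set(ids)
    t_clusters = {c.cluster_id for c in cluster_specs if c.t_lineage}
    for s in sharing_specs:
        for lab in s.cluster_pair:
            if lab not in known:
                raise SynocloneError(f"sharing spec references unknown cluster {lab}")
            if lab not in t_clusters:
                raise SynocloneError(f"sharing spec references non-T cluster {lab}")
    if lr_spec is not None:
        for p in lr_spec.pairs:
            for lab in (p.sender, p.receiver):
                if lab not in known:
                    raise SynocloneError(f"LR plant references unknown cluster {lab}")


def generate_dataset(
    cluster_specs: list[ClusterSpec],
    sharing_specs: list[CloneSharingSpec] | None = None,
    lr_spec: LRPlantSpec | None = None,
    n_patients: int = 8,
    doublet_rate: float = 0.0,
    seed: int = 0,
    tcr_coverage: float = DEFAULT_TCR_COVERAGE,
    n_housekeeping: int = 400,
    housekeeping_mean: float = 2.0,
    mito_mean: float = 9.0,
) -> tuple[CellGeneMatrix, pd.DataFrame, TruthSet]:
    """Generate a paired PB/SF dataset with planted ground truth.

    Returns (counts matrix, contig table, truth set).  Housekeeping genes
    give every cell a realistic library complexity; the five MT- genes
    contribute a plausible mitochondrial fraction (~5% of the library at
    the defaults).
    """
    sharing_specs = sharing_specs or []
    if not 0.0 <= doublet_rate <= 0.2:
        raise SynocloneError("doublet_rate must lie in [0, 0.2]")
    _validate_specs(cluster_specs, sharing_specs, lr_spec)
    rng = np.random.default_rng(seed)

    # ---- gene universe -------------------------------------------------
    genes: list[str] = []
    for c in cluster_specs:
        genes.extend(c.signature_genes)
    if lr_spec is not None:
        for p in lr_spec.pairs:
            for g in (p.ligand, p.receptor):
                if g not in genes:
                    genes.append(g)
    genes.extend(MITO_GENES)
    genes.extend(f"HK{i:04d}" for i in range(1, n_housekeeping + 1))
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # LR plants keyed by (gene, cluster) -> on fraction (max over plants)
    lr_on: dict[tuple[str, str], LRPlant] = {}
    if lr_spec is not None:
        for p in lr_spec.pairs:
            for gene, cluster, frac in (
                (p.ligand, p.sender, p.ligand_on_fraction),
                (p.receptor, p.receiver, p.receptor_on_fraction),
            ):
                key = (gene, cluster)
                if key not in lr_on or frac > lr_on[key][0]:
                    lr_on[key] = (frac, p.on_mean_extra)

    # ---- per-cluster count blocks -------------------------------------
    def nb(mean: float, r: float, size) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size, dtype=np.int64)
        return rng.negative_binomial(r, r / (r + mean), size=size)

    blocks: list[np.ndarray] = []
    cell_cluster: list[str] = []
    cell_patient: list[str] = []
    cell_comp: list[str] = []
    for c in cluster_specs:
        n_cells = c.n_cells_per_sample * n_patients
        block = nb(c.background_mean, c.dispersion, (n_genes, n_cells))
        sig_idx = [gene_pos[g] for g in c.signature_genes]
        block[sig_idx, :] = nb(c.signature_mean, c.dispersion, (len(sig_idx), n_cells))
        mito_idx = [gene_pos[g] for g in MITO_GENES]
        block[mito_idx, :] = nb(mito_mean, c.dispersion, (len(mito_idx), n_cells))
        hk_idx = np.arange(n_genes - n_housekeeping, n_genes)
        block[hk_idx, :] = nb(housekeeping_mean, c.dispersion, (n_housekeeping, n_cells))
        for (gene, cluster), (frac, extra) in lr_on.items():
            if cluster != c.cluster_id:
                continue
            gi = gene_pos[gene]
            on = rng.random(n_cells) < frac
            vals = np.zeros(n_cells, dtype=np.int64)
            vals[on] = 1 + rng.poisson(extra, size=int(on.sum()))
            block[gi, :] = vals
        blocks.append(block)
        cell_cluster.extend([c.cluster_id] * n_cells)
        patients = np.repeat([f"P{i+1}" for i in range(n_patients)], c.n_cells_per_sample)
        cell_patient.extend(patients.tolist())
        comp = np.where(rng.random(n_cells) < c.compartment_bias, "SF", "PB")
        cell_comp.extend(comp.tolist())

    counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_genes, 0), dtype=np.int64)
    n_singlets = counts.shape[1]

    # ---- doublets: gene-wise sum of two parents from distinct clusters --
    n_doublets = int(round(doublet_rate * n_singlets))
    cluster_arr = np.array(cell_cluster)
    doublet_cols = []
    doublet_cluster, doublet_patient, doublet_comp = [], [], []
    for _ in range(n_doublets):
        while True:
            i, j = rng.integers(0, n_singlets, size=2)
            if cluster_arr[i] != cluster_arr[j]:
                break
        doublet_cols.append(counts[:, i] + counts[:, j])
        doublet_cluster.append(cell_cluster[i])
        doublet_patient.append(cell_patient[i])
        doublet_comp.append(cell_comp[i])
    if doublet_cols:
        counts = np.concatenate([counts, np.stack(doublet_cols, axis=1)], axis=1)

    barcodes = _random_barcodes(rng, counts.shape[1])
    all_cluster = cell_cluster + doublet_cluster
    all_patient = cell_patient + doublet_patient
    all_comp = cell_comp + doublet_comp
    meta = pd.DataFrame(
        {
            "patient": all_patient,
            "compartment": all_comp,
            "sample_id": [f"{p}_{c}" for p, c in zip(all_patient, all_comp)],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    matrix = CellGeneMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"G{i:05d}" for i in range(n_genes)],
        gene_symbols=list(genes),
        barcodes=barcodes,
        cell_meta=meta,
    )

    # ---- clonotypes ----------------------------------------------------
    contigs, shared_truth = _generate_contigs(
        rng,
        cluster_specs,
        sharing_specs,
        barcodes[:n_singlets],
        cell_cluster,
        tcr_coverage,
    )

    truth = TruthSet(
        cell_cluster=dict(zip(barcodes, all_cluster)),
        doublet_barcodes=set(barcodes[n_singlets:]),
        shared_clone_ids=shared_truth,
        planted_lr={
            (p.ligand, p.receptor, p.sender, p.receiver)
            for p in (lr_spec.pairs if lr_spec else [])
            if p.positive
        },
        seed=seed,
    )
    return matrix, contigs, truth


def _generate_contigs(
    rng: np.random.Generator,
    cluster_specs,
    sharing_specs,
    barcodes,
    cell_cluster,
    tcr_coverage,
) -> tuple[pd.DataFrame, dict]:
    """Plant clonotypes in T-lineage clusters per the sharing specs."""
    t_clusters = [c.cluster_id for c in cluster_specs if c.t_lineage]
    # clone pools per cluster; shared clones listed first so geometric
    # expansion weights make them the most expanded (as in the study,
    # where the most expanded blood/synovial clones were the shared ones)
    clone_counter = 0
    pools: dict[str, list[dict]] = {t: [] for t in t_clusters}
    params: dict[str, CloneSharingSpec] = {}
    shared_truth: dict[tuple[str, str], set[str]] = {}
    default_spec = CloneSharingSpec(cluster_pair=("", ""))
    for spec in sharing_specs:
        a, b = spec.cluster_pair
        shared = []
        for _ in range(spec.n_shared_clones):
            clone_counter += 1
            shared.append(
                _make_clone(rng, clone_counter, rng.random() < spec.multi_chain_fraction)
            )
        pools[a].extend(shared)
        pools[b].extend(shared)
        key = tuple(sorted((a, b)))
        shared_truth[key] = {c["clone_id"] for c in shared}
        for lab in (a, b):
            params[lab] = spec
            for _ in range(spec.n_private_clones_per_cluster):
                clone_counter += 1
                pools[lab].append(
                    _make_clone(rng, clone_counter, rng.random() < spec.multi_chain_fraction)
                )
    for t in t_clusters:
        if not pools[t]:
            params[t] = default_spec
            for _ in range(DEFAULT_PRIVATE_CLONES):
                clone_counter += 1
                pools[t].append(
                    _make_clone(rng, clone_counter, rng.random() < default_spec.multi_chain_fraction)
                )

    rows: list[tuple] = []
    cluster_arr = np.array(cell_cluster)
    barcodes = np.array(barcodes)
    for t in t_clusters:
        pool = pools[t]
        spec = params[t]
        cells = barcodes[cluster_arr == t]
        covered = cells[rng.random(len(cells)) < tcr_coverage]
        if len(covered) < len(pool):
            raise SynocloneError(
                f"cluster {t}: {len(covered)} TCR-covered cells cannot seat "
                f"{len(pool)} planted clones; increase cells or reduce clones"
            )
        # seat one cell per clone (guarantees every planted clone is
        # observed, and every shared clone occupies both clusters) ...
        assignment = list(range(len(pool)))
        # ... then expand the rest geometrically over the pool
        p = max(spec.expansion_geometric_p, 1e-6)
        w = (1.0 - p) ** np.arange(len(pool))
        w /= w.sum()
        extra = rng.choice(len(pool), size=len(covered) - len(pool), p=w)
        assignment.extend(extra.tolist())
        for bc, ci in zip(covered, assignment):
            clone = pool[ci]
            for ch in clone["chains"]:
                rows.append(
                    (
                        bc,
                        ch["chain"],
                        ch["v_gene"],
                        ch["j_gene"],
                        ch["cdr3_nt"],
                        ch["cdr3_aa"],
                        True,
                        int(rng.integers(2, 40)),
                    )
                )
            if rng.random() < spec.nonproductive_fraction:
                junk = _make_clone(rng, 0, False)["chains"][0]
                rows.append(
                    (
                        bc,
                        junk["chain"],
                        junk["v_gene"],
                        junk["j_gene"],
                        junk["cdr3_nt"],
                        junk["cdr3_aa"],
                        False,
                        int(rng.integers(1, 5)),
                    )
                )
    contigs = pd.DataFrame(rows, columns=CONTIG_COLUMNS)
    return contigs, shared_truth


def simulate_null_membership(
    cluster_clone_counts: dict[str, int],
    universe_size: int,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Matched null for the repertoire-overlap test.

    Each cluster's clone set is drawn uniformly at random (without
    replacement) from a common universe, independently across clusters —
    no planted sharing, so any overlap is chance alone.  Used to check
    that the Fisher/BH machinery controls the false discovery rate.
    """
    rng = np.random.default_rng(seed)
    universe = [f"C{i:05d}" for i in range(1, universe_size + 1)]
    out = {}
    for label in sorted(cluster_clone_counts):
        k = cluster_clone_counts[label]
        if k > universe_size:
            raise SynocloneError(f"{label}: clone count exceeds universe")
        out[label] = set(rng.choice(universe, size=k, replace=False))
    return out


# ---------------------------------------------------------------------------
# default study-shaped specifications
# ---------------------------------------------------------------------------

def default_cluster_specs(n_cells_per_sample: int = 40) -> list[ClusterSpec]:
    """Six demo populations echoing the study's compartment skews:
    naive T and CX3CR1hi effector CD8 T enriched in blood, Tregs and
    CXCR3hi effector CD8 T enriched in synovial fluid."""
    return [
        ClusterSpec(
            "NaiveT", n_cells_per_sample,
            ["TCF7", "SELL", "CCR7", "LEF1", "IL7R", "MAL", "NOSIP", "RCAN3"],
            compartment_bias=0.25, t_lineage=True,
        ),
        ClusterSpec(
            "CX3CR1hi_CD8T", n_cells_per_sample,
            ["FGFBP2", "GZMH", "KLRG1", "TBX21", "S1PR5", "ADGRG1", "FCRL6", "PRF1"],
            compartment_bias=0.15, t_lineage=True,
        ),
        ClusterSpec(
            "CXCR3hi_CD8T", n_cells_per_sample,
            ["GZMK", "CD27", "CD8A", "EOMES", "CRTAM", "DUSP2", "CMC1", "CST7"],
            compartment_bias=0.85, t_lineage=True,
        ),
        ClusterSpec(
            "Treg", n_cells_per_sample,
            ["FOXP3", "IL2RA", "CTLA4", "TNFRSF4", "TNFRSF18", "BATF", "TIGIT", "IKZF2"],
            compartment_bias=0.9, t_lineage=True,
        ),
        ClusterSpec(
            "Myeloid", n_cells_per_sample,
            ["CD14", "LYZ", "S100A8", "S100A9", "FCN1", "VCAN", "CSF1R", "CD68"],
            compartment_bias=0.6,
        ),
        ClusterSpec(
            "B", n_cells_per_sample,
            ["CD19", "MS4A1", "CD79A", "CD79B", "IGHM", "TCL1A", "BANK1", "CD74"],
            compartment_bias=0.3,
        ),
    ]


def default_sharing_specs() -> list[CloneSharingSpec]:
    """Clone sharing planted between the blood CX3CR1hi and synovial
    CXCR3hi effector CD8 T populations, the axis the analysis tests.

    The naive-T/Treg pair shares nothing but carries many private clones,
    so the clone universe is large relative to the effector pair's clone
    counts and the planted sharing is a true enrichment.
    """
    return [
        CloneSharingSpec(
            cluster_pair=("CX3CR1hi_CD8T", "CXCR3hi_CD8T"),
            n_shared_clones=20,
            n_private_clones_per_cluster=30,
            expansion_geometric_p=0.1,
            nonproductive_fraction=0.1,
            multi_chain_fraction=0.027,
        ),
        CloneSharingSpec(
            cluster_pair=("NaiveT", "Treg"),
            n_shared_clones=0,
            n_private_clones_per_cluster=180,
            expansion_geometric_p=0.02,
            nonproductive_fraction=0.1,
            multi_chain_fraction=0.027,
        ),
    ]


def overlap_recovery_specs(
    n_t_clusters: int = 8,
    n_cells_per_sample: int = 15,
    n_shared: int = 20,
) -> tuple[list[ClusterSpec], list[CloneSharingSpec]]:
    """Spec set for repertoire-overlap recovery studies.

    ``n_t_clusters`` T populations; one pair (T0, T1) shares ``n_shared``
    clones on top of 30 privates each, the remaining clusters carry 60
    private clones each, giving a clone universe of roughly 500 at the
    defaults with 8 patients.
    """
    specs = [
        ClusterSpec(
            f"T{i}",
            n_cells_per_sample,
            [f"T{i}SIG{j}" for j in range(1, 9)],
            compartment_bias=0.5,
            t_lineage=True,
        )
        for i in range(n_t_clusters)
    ]
    sharing = [
        CloneSharingSpec(
            cluster_pair=("T0", "T1"),
            n_shared_clones=n_shared,
            n_private_clones_per_cluster=30,
        )
    ]
    for i in range(2, n_t_clusters - 1, 2):
        sharing.append(
            CloneSharingSpec(
                cluster_pair=(f"T{i}", f"T{i+1}"),
                n_shared_clones=0,
                n_private_clones_per_cluster=60,
            )
        )
    return specs, sharing


def default_lr_spec() -> LRPlantSpec:
    """Chemokine axis plants: myeloid CXCL9/10/11 -> T CXCR3, myeloid
    CXCL16 -> T CXCR6, myeloid CX3CL1 -> CX3CR1hi T, plus one decoy pair
    whose ligand stays under the 20% expression threshold."""
    return LRPlantSpec(
        pairs=[
            LRPlant("CXCL9", "CXCR3", "Myeloid", "CXCR3hi_CD8T", 0.6, 0.7),
            LRPlant("CXCL10", "CXCR3", "Myeloid", "CXCR3hi_CD8T", 0.6, 0.7),
            LRPlant("CXCL11", "CXCR3", "Myeloid", "CXCR3hi_CD8T", 0.5, 0.7),
            LRPlant("CXCL16", "CXCR6", "Myeloid", "CXCR3hi_CD8T", 0.6, 0.6),
            LRPlant("CX3CL1", "CX3CR1", "Myeloid", "CX3CR1hi_CD8T", 0.5, 0.8),
            LRPlant("CCL5", "CCR5", "Myeloid", "NaiveT", 0.08, 0.5),
        ]
    )


def demo_dataset(seed: int = 0, doublet_rate: float = 0.05, n_cells_per_sample: int = 40):
    """The default ~2,000-cell demo fixture (6 clusters, 8 patients)."""
    return generate_dataset(
        default_cluster_specs(n_cells_per_sample),
        default_sharing_specs(),
        default_lr_spec(),
        n_patients=8,
        doublet_rate=doublet_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture I/O (10x MatrixMarket convention)
# ---------------------------------------------------------------------------

def write_fixture(
    matrix: CellGeneMatrix,
    contigs: pd.DataFrame,
    truth: TruthSet,
    out_dir: str,
    overwrite: bool = False,
    gzipped: bool = False,
) -> dict[str, str]:
    """Write matrix.mtx + barcodes.tsv + features.tsv (10x convention),
    contigs.tsv, metadata.tsv and truth.json; returns the path map."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise SynocloneError(f"output dir not empty (pass overwrite=True): {out_dir}")
    os.makedirs(out_dir, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    opener = gzip.open if gzipped else open

    paths = {}
    mtx_path = os.path.join(out_dir, "matrix.mtx" + suffix)
    with opener(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(matrix.counts, dtype=np.int64), field="integer")
    paths["matrix"] = mtx_path

    bc_path = os.path.join(out_dir, "barcodes.tsv" + suffix)
    with opener(bc_path, "wt") as fh:
        fh.write("".join(b + "\n" for b in matrix.barcodes))
    paths["barcodes"] = bc_path

    ft_path = os.path.join(out_dir, "features.tsv" + suffix)
    with opener(ft_path, "wt") as fh:
        for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\n")
    paths["features"] = ft_path

    meta_path = os.path.join(out_dir, "metadata.tsv")
    matrix.cell_meta.reset_index().to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path

    contig_path = os.path.join(out_dir, "contigs.tsv")
    contigs.loc[:, CONTIG_COLUMNS].to_csv(contig_path, sep="\t", index=False)
    paths["contigs"] = contig_path

    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
    paths["truth"] = truth_path
    return paths


def read_truth(path: str) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_json(fh.read())
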