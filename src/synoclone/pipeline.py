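"""End-to-end orchestration: QC -> clustering -> doublet removal ->
re-clustering -> markers/annotation -> clonotype integration -> interactome.

Every stage reads and writes plain files under the run directory and the
manifest records every parameter, the seed, and input hashes, so a rerun
with an identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from . import __version__
from .datatypes import ClusterAssignment, SynocloneError
from .interactome import (
    differential_interactome,
    expressed_genes,
    load_lr_pairs,
    match_lr_pairs,
    score_interactions,
)
from .io_qc import (
    QCThresholds,
    apply_qc_filters,
    compute_cell_qc,
    flag_doublets,
    read_contigs,
    read_matrix,
    write_filter_report,
)
from .phenotype import (
    ClusteringParams,
    annotate_clusters,
    compartment_composition,
    find_markers,
    load_marker_rules,
    normalize_log,
)
from .phenotype import cluster_cells as _cluster_cells
from .repertoire import (
    call_clonotypes,
    overlap_matrix,
    overlap_test,
    top_expanded,
    universe_size_of,
)
from .synthetic import demo_dataset, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_dir: str
    out_dir: str
    contigs: str | None = None
    lr_list: str | None = None
    lineage_sets: str | None = None  # YAML: lineage name -> gene list
    marker_rules: str | None = None  # YAML: annotation rules
    seed: int = 0
    qc: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)  # overrides for the major round
    repertoire: dict = field(default_factory=dict)  # top_n, q_threshold, scope
    interactome: dict = field(default_factory=dict)  # frac_threshold, senders, receivers
    paired_composition: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SynocloneError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = os.path.dirname(os.path.abspath(path))
        for attr in ("matrix_dir", "out_dir", "contigs", "lr_list", "lineage_sets", "marker_rules"):
            v = getattr(cfg, attr)
            if v is not None and not os.path.isabs(v):
                setattr(cfg, attr, os.path.join(base, v))
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON).

    A failure in any stage leaves prior outputs in place and records a
    machine-readable error in the manifest before re-raising.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "input_hashes": {},
        "stages": {},
    }
    for name in ("contigs", "lr_list", "lineage_sets", "marker_rules"):
        p = getattr(config, name)
        if p and os.path.exists(p):
            manifest["input_hashes"][name] = _sha256(p)
    for fname in ("matrix.mtx", "matrix.mtx.gz", "barcodes.tsv", "features.tsv", "metadata.tsv"):
        p = os.path.join(config.matrix_dir, fname)
        if os.path.exists(p):
            manifest["input_hashes"][fname] = _sha256(p)

    def finish(stage: str, status: str, **extra) -> None:
        manifest["stages"][stage] = {"status": status, **extra}
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    stage = "read"
    try:
        matrix = read_matrix(config.matrix_dir)
        finish(stage, "ok", n_cells=matrix.n_cells, n_genes=matrix.n_genes)

        stage = "qc"
        thresholds = QCThresholds(**config.qc)
        qc_table = compute_cell_qc(matrix, thresholds)
        _write_tsv(qc_table.reset_index(), os.path.join(config.out_dir, "cell_qc.tsv"))
        filtered, report = apply_qc_filters(matrix, qc_table, thresholds)
        write_filter_report(report, os.path.join(config.out_dir, "filter_report.tsv"))
        finish(stage, "ok", removed=report.n_removed, retained=report.n_retained)

        stage = "cluster_initial"
        norm = normalize_log(filtered)
        params = ClusteringParams(round_id="major", seed=config.seed, **config.clustering)
        initial = _cluster_cells(norm, params)
        finish(stage, "ok", n_clusters=len(initial.cluster_names))

        stage = "doublets"
        if config.lineage_sets:
            with open(config.lineage_sets) as fh:
                lineage_sets = {k: list(v) for k, v in yaml.safe_load(fh).items()}
            flags = flag_doublets(filtered, initial, lineage_sets)
            _write_tsv(flags.reset_index(), os.path.join(config.out_dir, "doublet_flags.tsv"))
            keep = [b for b in filtered.barcodes if not flags.loc[b, "is_doublet"]]
            n_flagged = int(flags["is_doublet"].sum())
        else:
            keep = list(filtered.barcodes)
            n_flagged = 0
        clean = filtered.subset_cells(keep)
        norm = norm.subset_cells(keep)
        finish(stage, "ok", flagged=n_flagged, retained=len(keep))

        stage = "cluster_final"
        assignment = _cluster_cells(norm, params)
        _write_tsv(
            assignment.labels.rename("cluster").reset_index(),
            os.path.join(config.out_dir, "clusters.tsv"),
        )
        finish(stage, "ok", n_clusters=len(assignment.cluster_names))

        stage = "markers"
        markers = find_markers(norm, assignment)
        _write_tsv(markers, os.path.join(config.out_dir, "markers.tsv"))
        annotation = {}
        if config.marker_rules:
            rules = load_marker_rules(config.marker_rules)
            annotation = annotate_clusters(markers, rules)
            _write_tsv(
                pd.DataFrame(
                    sorted(annotation.items()), columns=["cluster", "label"]
                ),
                os.path.join(config.out_dir, "annotation.tsv"),
            )
        finish(stage, "ok", n_marker_rows=len(markers), annotation=annotation)

        stage = "composition"
        fractions, tests = compartment_composition(
            assignment, clean.cell_meta, paired=config.paired_composition
        )
        _write_tsv(fractions.reset_index(), os.path.join(config.out_dir, "composition_fractions.tsv"))
        _write_tsv(tests, os.path.join(config.out_dir, "composition_tests.tsv"))
        finish(stage, "ok")

        stage = "repertoire"
        if config.contigs and os.path.exists(config.contigs):
            contigs = read_contigs(config.contigs)
            clones = call_clonotypes(contigs)
            _write_tsv(clones.clones, os.path.join(config.out_dir, "clones.tsv"))
            rep_cfg = {"top_n": 100, "q_threshold": 0.05, "scope": "per_compartment"}
            rep_cfg.update(config.repertoire)
            ranked, count_matrix = top_expanded(
                clones,
                assignment,
                clean.cell_meta,
                n=int(rep_cfg["top_n"]),
                scope=rep_cfg["scope"],
            )
            _write_tsv(ranked, os.path.join(config.out_dir, "top_clones.tsv"))
            _write_tsv(count_matrix.reset_index(), os.path.join(config.out_dir, "top_clone_counts.tsv"))
            counts = overlap_matrix(clones, assignment)
            _write_tsv(counts.reset_index(), os.path.join(config.out_dir, "overlap_counts.tsv"))
            tests = overlap_test(
                counts, universe_size_of(clones), q_threshold=float(rep_cfg["q_threshold"])
            )
            _write_tsv(tests, os.path.join(config.out_dir, "overlap_tests.tsv"))
            finish(stage, "ok", n_clones=clones.n_clones)
        else:
            finish(stage, "skipped", reason="no contig table configured")

        stage = "interactome"
        if config.lr_list and os.path.exists(config.lr_list):
            lr = load_lr_pairs(config.lr_list)
            int_cfg = {"frac_threshold": 0.2, "senders": None, "receivers": None}
            int_cfg.update(config.interactome)
            expr = expressed_genes(norm, assignment, frac_threshold=float(int_cfg["frac_threshold"]))
            calls = score_interactions(
                match_lr_pairs(expr, lr, int_cfg["senders"], int_cfg["receivers"])
            )
            diff = differential_interactome(markers, lr)
            calls["significant"] = [
                ((diff["ligand"] == l) & (diff["receptor"] == r)).any()
                for l, r in zip(calls["ligand"], calls["receptor"])
            ]
            _write_tsv(calls, os.path.join(config.out_dir, "interactions.tsv"))
            _write_tsv(diff, os.path.join(config.out_dir, "differential_interactome.tsv"))
            finish(stage, "ok", n_calls=len(calls))
        else:
            finish(stage, "skipped", reason="no LR list configured")
    except Exception as exc:  # noqa: BLE001 - recorded then re-raised
        finish(stage, "error", error=str(exc))
        raise
    return manifest


def make_demo(out_dir: str, seed: int = 0, doublet_rate: float = 0.05) -> str:
    """Write the default synthetic dataset and a ready-to-run config.

    Returns the config path.  The fixture: 6 clusters (naive T, blood
    CX3CR1hi and synovial CXCR3hi effector CD8 T, Treg, myeloid, B) from
    8 patients with paired PB/SF, clone sharing planted between the two
    effector CD8 populations, planted chemokine ligand-receptor axes,
    and 5% doublets.
    """
    os.makedirs(out_dir, exist_ok=True)
    fixture_dir = os.path.join(out_dir, "fixture")
    matrix, contigs, truth = demo_dataset(seed=seed, doublet_rate=doublet_rate)
    write_fixture(matrix, contigs, truth, fixture_dir, overwrite=True)

    ref = resources.files("synoclone.data").joinpath("lr_pairs_demo.tsv")
    with resources.as_file(ref) as p:
        shutil.copy(p, os.path.join(out_dir, "lr_pairs.tsv"))

    lineage_sets = {
        "NaiveT": ["TCF7", "SELL", "CCR7", "LEF1", "IL7R", "MAL", "NOSIP", "RCAN3"],
        "CX3CR1hi_CD8T": ["FGFBP2", "GZMH", "KLRG1", "TBX21", "S1PR5", "ADGRG1", "FCRL6", "PRF1"],
        "CXCR3hi_CD8T": ["GZMK", "CD27", "CD8A", "EOMES", "CRTAM", "DUSP2", "CMC1", "CST7"],
        "Treg": ["FOXP3", "IL2RA", "CTLA4", "TNFRSF4", "TNFRSF18", "BATF", "TIGIT", "IKZF2"],
        "Myeloid": ["CD14", "LYZ", "S100A8", "S100A9", "FCN1", "VCAN", "CSF1R", "CD68"],
        "B": ["CD19", "MS4A1", "CD79A", "CD79B", "IGHM", "TCL1A", "BANK1", "CD74"],
    }
    with open(os.path.join(out_dir, "lineage_sets.yaml"), "w") as fh:
        yaml.safe_dump(lineage_sets, fh, sort_keys=True)

    rules = [
        {"label": "Naive T", "required": ["TCF7", "SELL"], "forbidden": ["CD14"]},
        {"label": "CX3CR1hi effector CD8 T", "required": ["FGFBP2", "GZMH"], "forbidden": []},
        {"label": "CXCR3hi effector CD8 T", "required": ["GZMK", "CD27"], "forbidden": []},
        {"label": "Treg", "required": ["FOXP3", "IL2RA"], "forbidden": []},
        {"label": "Myeloid", "required": ["CD14", "LYZ"], "forbidden": ["CD19"]},
        {"label": "B", "required": ["CD19", "MS4A1"], "forbidden": ["CD14"]},
    ]
    with open(os.path.join(out_dir, "marker_rules.yaml"), "w") as fh:
        yaml.safe_dump(rules, fh, sort_keys=True)

    config = {
        "matrix_dir": "fixture",
        "contigs": os.path.join("fixture", "contigs.tsv"),
        "lr_list": "lr_pairs.tsv",
        "lineage_sets": "lineage_sets.yaml",
        "marker_rules": "marker_rules.yaml",
        "out_dir": "run",
        "seed": seed,
        "qc": {"min_genes": 200, "max_genes": 6500, "max_pct_mito": 15.0},
        # major-round defaults scaled to the fixture's size: the 200-neighbor
        # graph of the full study is far larger than any single planted
        # population here
        "clustering": {"n_hvg": 2000, "n_pcs": 40, "k_neighbors": 30, "resolution": 0.6},
        "repertoire": {"top_n": 100, "q_threshold": 0.05, "scope": "per_compartment"},
        "interactome": {"frac_threshold": 0.2},
    }
    cfg_path = os.path.join(out_dir, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
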