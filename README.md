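# synoclone

Analysis pipeline for paired blood / synovial-fluid single-cell studies of
inflammatory arthritis, built for datasets that combine 5' scRNA-seq with
single-cell TCR sequencing per patient and compartment (peripheral blood,
PB, and synovial fluid, SF).

It is aimed at computational immunologists who want the standard stages of
such an analysis as tested, reusable library functions rather than a
notebook: cell-level quality control and multi-step doublet removal,
graph-based clustering with declarative marker annotation, clonotype
calling with a repertoire-overlap statistic, ligand–receptor interactome
calling, and the closed-form functional-assay scores used on the clinical
side (Treg percent suppression, chemokine migration ratio, CDAI).

Because the patient data such pipelines are built for sit under controlled
access, the package ships a first-class synthetic-data generator that
emulates the study structure — negative-binomial cluster-structured UMI
counts, paired PB/SF samples per patient, clonal expansion with planted
cross-compartment clone sharing, doublets as sums of two parent cells, and
planted chemokine ligand/receptor axes (myeloid CXCL9/10/11/16 senders
versus T-cell CXCR3/CXCR6 receivers). Every stage is tested against the
generator's recorded ground truth.

## The statistics at the core

**Repertoire overlap.** A clonotype is the exact set of productive
(chain, V, J, CDR3-nucleotide) tuples carried by a cell. For clusters
*A*, *B* with clone sets of sizes $n_A$, $n_B$ drawn from a universe of
$N$ distinct clonotypes, the observed number of shared clones $s$ is
tested with a one-sided Fisher exact test on the table
$[[s,\; n_A-s],[n_B-s,\; N-n_A-n_B+s]]$, i.e. the hypergeometric upper
tail $P[X \ge s]$, followed by Benjamini–Hochberg FDR adjustment across
all cluster pairs; pairs with $q<0.05$ are called significant.

**Expression calling for the interactome.** A ligand or receptor is
"expressed" in a cluster when strictly more than 20% of its cells have
$\log_2(\text{normalized UMI}+1) > 0$. A call (ligand, receptor,
sender → receiver) is emitted when both sides are expressed; the edge
weight is the product of the two mean log-normalized expressions.

**Cell QC.** Cells with <200 detected genes, >15% mitochondrial
transcripts, or >6500 detected genes are removed (strict inequalities —
boundary cells retained), then doublets are flagged as the union of
high library complexity, hybrid lineage-marker expression, wholesale
hybrid clusters, and an optional external doublet score.

**Assay scores.** Percent suppression
$= 100 - 100\cdot\frac{\%\ \text{responding with Treg}}{\%\ \text{responding without Treg}}$;
migration ratio = bead-standardized migrated events with chemokine over
without; CDAI = patient global (0–10) + physician global (0–10) +
swollen (0–28) + tender (0–28) joint counts, banded as remission
(0–2.8], low (2.8–10.0], moderate (10.0–22.0], high (>22).

## Worked example

```python
import pandas as pd
from synoclone.synthetic import demo_dataset
from synoclone.datatypes import ClusterAssignment
from synoclone.repertoire import (
    call_clonotypes, overlap_matrix, overlap_test, universe_size_of,
)

matrix, contigs, truth = demo_dataset(seed=3, doublet_rate=0.0)
labels = pd.Series({b: truth.cell_cluster[b] for b in matrix.barcodes})
assignment = ClusterAssignment(labels=labels.loc[matrix.barcodes], round_id="truth")

clones = call_clonotypes(contigs)
print(f"{matrix.n_cells} cells, {clones.n_clones} clonotypes")
tests = overlap_test(overlap_matrix(clones, assignment), universe_size_of(clones))
print(tests[tests.significant][["cluster_a", "cluster_b", "n_shared",
                                "p_one_sided", "q_bh"]].to_string(index=False))
```

prints

```
1920 cells, 440 clonotypes
    cluster_a    cluster_b  n_shared  p_one_sided         q_bh
CX3CR1hi_CD8T CXCR3hi_CD8T        20 1.276888e-08 7.661326e-08
```

The generator planted 20 shared clonotypes between the blood CX3CR1hi
and synovial CXCR3hi effector CD8 T populations; the overlap test finds
exactly that pair significantly enriched (all 5 other pairs have
$p = 1$). Assay scores work the same way:
`percent_suppression(SuppressionAssay(pct_with_treg=20, pct_without_treg=80))`
returns `75.0` — Tregs cutting responder proliferation from 80% to 20%
is 75% suppression.

The full pipeline runs from the command line:

```sh
synoclone demo --out demo --seed 0     # write fixture + config
synoclone run -c demo/config.yaml      # QC -> clusters -> TCR -> interactome
```

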