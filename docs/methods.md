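# Methods

## Scope and data model

The package analyses paired peripheral-blood (PB) / synovial-fluid (SF)
single-cell datasets: a sparse genes × cells raw UMI matrix in the 10x
MatrixMarket convention with per-barcode metadata (patient, compartment,
sample), a per-chain V(D)J contig table emulating `cellranger vdj`
filtered-contig output, and a curated ligand–receptor pair list. All
containers are thin wrappers over scipy sparse matrices and pandas
tables; invariants (label/dimension agreement, barcode uniqueness,
nonnegative integer counts) are checked at construction.

## Quality control

Per-cell quantities are detected genes, total UMIs, and the
mitochondrial percentage (UMIs on symbols with prefix `MT-`,
case-insensitive, over total; defined as 0 for empty cells). Filters use
strict inequalities — `<200` genes, `>15%` mitochondrial, `>6500` genes
— so boundary cells (exactly 200 genes, exactly 15.0%) are retained.
The rules apply as a union and the filter report counts removals per
rule; filtering is idempotent.

Doublet flagging is a multi-step union applied after an initial
clustering round:

1. *library complexity* — detected genes above the same 6500 cap;
2. *hybrid markers* — a cell whose cluster lineage is L but which
   detects ≥ k genes (default k = 2) of a different lineage's marker
   set at UMI > 0. One off-lineage gene is too noisy a criterion for
   sparse UMI data, hence the default of two;
3. *hybrid clusters* — a whole cluster whose mean per-cell detected
   marker count reaches the threshold for two or more lineage sets is
   flagged wholesale;
4. *external score* — an optional precomputed doublet score column with
   a cutoff, so any external algorithm can slot into the union without
   being re-implemented here.

The flag/recompute cycle iterates until no new flags appear (lineage
inference can shift once flagged cells are set aside); the iteration
count and k are parameters because no principled single value exists.

## Normalization and clustering

Expression is normalized per cell to a library size of 10,000 and
log-transformed in base 2: `log2(count / total * 1e4 + 1)`. Base 2 is
used throughout so that every downstream threshold (marker detection at
value > 0, the interactome's 20% rule) is stated in one unit.

Clustering follows the standard graph pipeline: top-2000 highly variable
genes, per-gene z-scaling clipped at ±10 (to bound outlier leverage),
PCA, a k-nearest-neighbor graph in PC space, conversion to a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights (pruned
below 1/15), and seeded Leiden modularity optimization with a resolution
parameter. Three configured rounds mirror the intended analysis design:
a major round (40 PCs, 200 neighbors, resolution 0.6), an NK/NKT/T
subclustering round (30, 30, 0.8), and a Treg subclustering round
(30, 30, 0.1). PC count is a parameter, not automated elbow detection.

HVG selection ranks genes by the variance of their log-normalized
expression. A mean-trend-corrected standardized variance (the `vst`
family) differs mainly for depth-confounded genes; on library-size
normalized values the plain variance ranking selects the same
cluster-discriminating genes, and it keeps the selection exactly
reproducible with no smoothing hyperparameters.

Determinism: cells are canonically ordered (barcode-sorted) before the
pipeline, PCA signs are fixed by convention, Leiden is seeded, and
labels are renamed by decreasing cluster size — so the partition is
invariant to input cell order and identical across reruns.

Markers are found cluster-vs-rest with the Wilcoxon rank-sum test on
normalized values, testing genes detected in ≥ 20% of in- or out-cluster
cells; p-values are exact (enumeration) when both groups have ≤ 8
tie-free observations and tie-corrected normal otherwise; log2 fold
change is the difference of in/out mean log2 expression; q-values are
Benjamini–Hochberg across all tests. Annotation is declarative: a
cluster earns a rule's label when all required genes are significant
markers (q < 0.05, log2FC above the rule floor) and no forbidden gene
is; several matches give "ambiguous", none gives "unassigned".

Compartment composition uses per-sample cluster fractions (summing to 1
per sample) compared PB-vs-SF with a two-sided paired t test across
patients when both compartments are present (unpaired otherwise), and a
one-way ANOVA with Bonferroni-adjusted pairwise t tests for ≥ 3 groups.

## Clonotypes and repertoire overlap

Clonotype identity is the exact set of productive (chain, V, J,
CDR3-nucleotide) tuples of a cell, restricted to TRA/TRB; nonproductive
contigs are discarded and cells without a productive chain are absent.
Multi-chain cells (more than one TRA or TRB) keep all productive chains
in the signature and therefore form their own clones unless signatures
match exactly. No fuzzy CDR3 matching is performed — exact nucleotide
identity is the conservative reading of clonal descent.

The clonal fraction of a clone in a sample is its cells over the
sample's clone-bearing cells. Expansion ranking returns the top-n clones
(default 100) per compartment or per sample, ties broken by total cells
across the dataset and then clone id.

Repertoire overlap between clusters *A* and *B* counts clones with at
least one member cell in each (the occupancy threshold is configurable).
The significance test treats the dataset's distinct clonotypes as the
universe *N* and asks whether the observed shared count is enriched
relative to drawing *A*'s and *B*'s clone sets independently: a
one-sided Fisher exact test on
[[shared, A-only], [B-only, N − A∪B]], i.e. the hypergeometric upper
tail, followed by BH adjustment over all tested pairs with significance
at q < 0.05. The 2×2 construction and the cutoff are declared normative
here and parameterized.

## Ligand–receptor interactome

A gene is expressed in a cluster when strictly more than 20% of cells
have log2(normalized UMI + 1) > 0 — strict at both the cell-level and
fraction-level cuts. Calls require the ligand expressed in the sender
and the receptor in the receiver; both directions and self-pairs are
evaluated, and cluster roles can be restricted (e.g. myeloid senders,
T receivers). The interaction score is the product of the mean
log-normalized ligand and receptor expression: a surrogate magnitude
chosen to preserve "higher expression, thicker edge" semantics and to
vanish when either side is silent — it is not a statistical quantity.
The differential interactome intersects the pair list with significant
cluster markers (q < 0.05, detection ≥ 20%) and names the differential
side; the `significant` flag on calls means membership in that set. No
permutation test is attached to calls.

## Assay scores

Percent suppression is `100 − 100·(with Treg)/(without Treg)` on the
percentage of proliferating or cytokine-secreting responder cells; it is
undefined when the no-Treg response is zero and negative values
(enhancement) are returned unclamped — they are biologically meaningful.
The migration ratio standardizes migrated-cell events by bead-spike
events in each tube, then divides chemokine by control; it is invariant
to rescaling both bead counts. CDAI sums patient global (0–10),
physician global (0–10), and swollen/tender counts of 28 joints; bands
are resolved as half-open intervals [0, 2.8], (2.8, 10.0],
(10.0, 22.0], (22, ∞), so a total of exactly 22 is moderate. The
component maxima make the attainable range 0–76. Paired comparisons
offer the one-sided Wilcoxon matched-pairs signed-rank test (zeros
dropped, exact sign-enumeration p for ≤ 15 untied pairs, normal
approximation above) and the two-sided paired t test, with identical
vectors defined as (t = 0, p = 1).

## The synthetic-data generator

The generator emulates what the analysis assumes about real data:

* **Counts.** Negative binomial per gene per cluster (the standard
  overdispersed UMI model, with the inverse-dispersion a testable knob,
  default r = 2). Each cluster has 8 disjoint signature genes (mean 5
  inside, 0.005 outside); 400 housekeeping genes (mean 2) give every
  cell a realistic library complexity (~300 detected genes), and five
  `MT-` genes (mean 9) contribute ~5% mitochondrial fraction.
* **Study design.** 8 patients with paired PB/SF; each cluster's cells
  land in SF with its compartment bias, echoing populations distinctly
  present in blood (naive T, CX3CR1hi effector CD8 T) or joint fluid
  (Treg, CXCR3hi effector CD8 T).
* **Doublets.** Gene-wise sums of two parent cells from different
  clusters — which makes them detectable exactly by hybrid markers and
  elevated library size, matching the QC criteria.
* **Clonotypes.** Only T-lineage clusters receive contigs; 69% of T
  cells carry at least one productive chain (the coverage observed in
  this assay class). Clones are paired TRA+TRB with V/J and stop-free
  CDR3s; ~2.7% carry an extra chain; a configurable fraction of cells
  gains a nonproductive extra contig. Every planted clone is seated in
  one cell first (so shared clones occupy both clusters by
  construction), then remaining cells draw clones with geometrically
  decaying weights, making early (shared) clones the most expanded —
  the expansion law is a modeling choice, not an inference. The default
  demo plants 20 shared clones between the two effector CD8
  populations inside a ~440-clone universe sized so the sharing is a
  genuine enrichment under the hypergeometric null.
* **Ligand–receptor axes.** Planted per (gene, cluster) as a Bernoulli
  on-fraction per cell; positives use fractions well above the caller's
  0.20 threshold, decoys keep one side below it.
* **Null model.** For calibration studies, a matched null draws each
  cluster's clone set uniformly and independently from the universe, so
  any overlap is chance and the Fisher null is exact by construction.

What the generator does **not** emulate: batch effects (correction is a
pluggable no-op hook here), ambient RNA, realistic gene-name universes
beyond the marker panel, depth gradients between compartments, or
continuous/overlapping cell states. Passing tests therefore demonstrate
correctness of the statistical machinery and recovery under the stated
generative model — not robustness to the full messiness of patient data.

## Problem sizes and numerical choices

The default fixtures are ~2,000 cells × ~460 genes (6 clusters × 40
cells/sample × 8 patients), and the overlap-recovery fixture is 8 T
clusters with a ~460-clone universe — sizes chosen so the whole suite
and the acceptance script run in about a minute while every statistic
operates far from degenerate regimes. Fisher p-values use scipy's
hypergeometric survival function (checked in tests against exact
rational-arithmetic enumeration for all universes ≤ 30); BH uses
statsmodels (checked against the naive step-up rule); the Wilcoxon and
rank-sum tests use scipy with explicit exact/asymptotic mode selection.
All randomness flows from one integer seed through a single numpy
Generator; no global RNG state is touched.

## Known limitations

* The interactome score is a declared surrogate; published scoring
  schemes for curated-pair interactomes differ and no claim of
  equivalence is made.
* The overlap test conditions on clone-set sizes and the observed
  universe; clones spanning more than two clusters enter every pairwise
  table, so pairs are not independent — BH is applied in its usual
  positive-dependence-tolerant role.
* Hybrid-marker doublet detection requires lineage marker sets that are
  actually disjoint in expression; closely related subpopulations (e.g.
  two T subsets sharing most markers) would need the external-score
  step to reach high sensitivity.
* `cluster_cells` requires more cells than neighbors; the 200-neighbor
  major-round default is meant for full-scale datasets and is scaled
  down (k = 30) in the bundled demo config.
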