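# Methods

## Scope and data model

The pipeline processes two kinds of single-cell measurements over a
targeted gene panel:

1. a cells × probes matrix of nonnegative molecule counts, with a panel
   annotation classing every probe as `endogenous`, `housekeeping`,
   `spike_in` or `negative`, and per-cell metadata giving a source class
   (`regular`, `tail`, `sox10mut`, `control_mel`, `control_iri`) and
   optionally the embryonic stage in hours post-fertilisation;
2. a cells × assays matrix of qPCR cycle-threshold (Ct) values in
   [0, 40], with the sentinels *Undetermined* (no signal within 40 cycles)
   and *missing* (failed reaction).

Count matrices carry a `stage_tag` recording their position in the QC
cascade (`raw → background_corrected → normalized → floored → imputed →
logged`); every operation validates the tag, so stages cannot be run out
of order. All interchange is delimited text.

## Count QC and normalization cascade

Stages, in fixed order, with defaults:

- **Cell signal filter** — cells whose summed *endogenous* counts fall
  below `min_total` (default 100) are removed (`low_signal`). Control
  probes are excluded from the sum: a lysate can carry abundant spike-in
  yet no usable biology.
- **Probe prevalence filter** — endogenous probes detected (count ≥ 1) in
  fewer than `min_cells` (default 3) cells are removed; control probes are
  never removed.
- **Background correction** — per cell, background = mean + 2·sd (sample
  sd) of the negative probes, subtracted from all non-negative-class
  entries and clipped at zero; cells whose endogenous signal is entirely
  below background are removed (`noisy_background`). With fewer than two
  negative probes the stage is skipped with a log notice.
- **Reference normalization** — per-cell factor
  f_c = mean over cells of the housekeeping+spike-in sum, divided by that
  cell's sum; all entries scaled by f_c. Cells with f_c outside
  `(1/3, 3)` are removed (`poor_norm_factor`). After scaling, every
  surviving cell's reference sum equals the pre-normalization mean.
- **Floor** — entries strictly below 30 (normalized counts) are set to 0.
  Targeted-panel counts under ~30 molecules are dominated by background
  hybridization.
- **Dropout imputation** — a consensus over k-means partitions
  (k ∈ {5, 6, 7}) of rank-transformed cell profiles (ranks make the
  Euclidean k-means geometry a Spearman-correlation surrogate). For each
  zero entry and each k, the candidate is the mean of the *nonzero* values
  of that probe among the cell's cluster-mates; the final value averages
  candidates across ks. Zeros with no donors stay zero; **nonzero entries
  are never modified** (asserted by tests entry-wise and as a multiset).
- **Log transform** — x → log2(1 + x).

After normalization the control probes have served their purpose and are
dropped: clustering, markers and trajectories operate in the endogenous
gene space (42 genes with the default panel). Keeping near-constant,
high-magnitude reference probes would compress cosine distances between
every pair of cells.

### Choice of imputation granularity

The consensus k must sit near the number of distinct expression programs
in the cohort. Too coarse (k ≈ 3–4) and each k-means cluster spans several
cell types, so the donor means import, e.g., iridophore genes into
progenitor cells and distinct centroids collapse toward each other. Too
fine (k ≈ 10–15) and clusters re-form around shared dropout patterns: the
cells missing a given gene are grouped together, have no donors for it,
and emerge as a spurious, perfectly separable sub-cluster. k ∈ {5, 6, 7}
matches the ~6 expression programs of the default cohort and shows neither
failure mode. If your panel/cohort differs, set `impute_ks` to bracket
your expected number of programs.

## Embedding and control-anchored clustering

The 2-D embedding is UMAP with `min_dist=4, spread=9, n_neighbors=25`,
cosine metric (tSNE with `perplexity=20`, exact gradients, learning rate
500 is available as an alternative but is not searched by default). The
transform can be fitted on a cell subset — by default the wild-type
sources — and then applied to all cells, so that mutant cells can be
projected into a WT-defined coordinate system. tSNE has no out-of-sample
transform in the underlying implementation, so its fit subset is ignored
with a warning.

Clustering is community detection (Leiden, RB-configuration modularity at
a tunable resolution) on the shared-nearest-neighbor graph of the
embedding: k-nearest-neighbor edges weighted by the Jaccard overlap of the
endpoints' neighbor sets, pruned below 1/15.

Because the embedding is stochastic, the search enumerates a grid of
(embedding parameters, resolution) pairs, runs every combination
`replicates=3` times with distinct seeds derived from the master seed, and
scores each partition with

qual = (1 + N_irido)/√(1 + N_clust_irido) + (1 + N_melo)/√(1 + N_clust_melo)

For each control type the target cluster is the one containing the most
cells of that type; ties go to the smaller cluster (purity), then the
lower cluster id; an absent control set contributes 1. The argmax solution
is kept, ties breaking toward the lowest grid index then replicate; the
full score table is emitted for audit. The search scores partitions
*before* merging; merging is applied to the winner.

**Merging.** For each cluster pair, a nearest-centroid classifier on the
union of the two clusters' top-4 markers (ranked by mean log-expression
difference cluster-vs-rest, ties alphabetical) is evaluated by stratified
5-fold cross-validation; pairs scoring below 0.9 accuracy are merged,
repeatedly, scanning pairs in canonical order. Clusters holding the
majority of control melanocytes or iridophores are never merged away.

The configured default grid spans min_dist ∈ {2,4,6}, spread ∈ {6,9,12},
n_neighbors ∈ {15,25,35}, resolution 0.4–1.6 (step 0.2), centred on the
published embedding parameters. The analysis drivers and the acceptance
script use the centre point with three resolutions {0.6, 1.0, 1.4} × 3
replicates — on the ~600-cell synthetic cohort this already recovers the
planted types with ARI ≥ 0.93 across seeds, and it keeps a full run in
tens of seconds.

## Lineages and pseudotime

Cluster centroids (arithmetic means in the logged endogenous space) are
joined by a minimum spanning tree under cosine distance (Kruskal;
deterministic tie-break by weight, then the lexicographically smallest
cluster pair). A lineage is the unique tree path from a designated start
cluster to each designated terminal; start/terminals are user-supplied
(`suggest_anchors` proposes candidates from tail-cell and control
enrichment but never auto-commits).

Pseudotime: all centroids and cell vectors are L2-normalized (making
Euclidean projections order-consistent with the cosine metric used for the
tree); a cell of the cluster at path index *i* is projected, clamped, onto
the polyline segment arriving at its cluster's centroid (start-cluster
cells use the first outgoing segment); pseudotime is the arc length from
the start centroid to the projection. Restricting each cell to its own
cluster's incoming segment — rather than the globally nearest segment —
guarantees that lineages sharing a path prefix assign *identical*
pseudotime to cells of the shared clusters, which keeps the two
pigment-fate lineages comparable over their common progenitor segment.
Principal-curve refinement is deliberately omitted: the pipeline's
trajectory claims are ordinal (stage ordering), not metric.

With a weakly differentiated melanocyte bridge the tree occasionally
routes the melanocyte path through the xanthophore cluster (both share
*mitfa*-positive ancestry in the generator); the shared progenitor prefix
and the pseudotime–stage ordering are unaffected.

## TaqMan processing

Sample QC rejects cells on the control assays with strict inequalities:
kanamycin Ct < 14 (poorly amplified) or rpl13 Ct < 24 (poor RNA quality or
empty well). Because low Ct normally means *high* signal, the comparison
direction is configurable (`reject_low=False` flips it); the default
follows the printed convention.

The cascade, in order: (1) Expression = (40 − Ct)·log10(2) per entry,
Undetermined → Ct 40 → 0, missing → NA (the per-cycle fold change is 2;
expressions are in log10 units, so Ct 24 → 4.816); (2) drop the
⌈0.05·n⌉ cells with the highest kanamycin expression (ties by cell id);
(3) subtract each cell's kanamycin expression from all its values;
(4) NA → 0; (5) drop the ⌈0.05·n⌉ cells with the lowest total expression;
(6) subtract the global matrix minimum (the output minimum is exactly 0);
(7) nullify values below the 4.8 noise floor. Steps 6–7 are idempotent on
their own output. Trims are count-based (⌈frac·n⌉ extreme cells, not
quantile interpolation) for exact reproducibility at small n. Fewer than
three remaining cells at any step is a hard error.

"Detectable" for a Ct assay means numeric Ct at or below a cutoff
(default 29); Undetermined and missing never qualify.

## Detection and reports

Counts are binarized at ≥ 30 (the analysis floor) by default, with a
documented ≥ 5 override for low-expression panels such as the sox10-mutant
display. Co-expression summaries report, among cells positive for an
anchor gene, the fraction positive for at least one gene of a query set;
an anchor with zero positive cells raises an explicit undefined-fraction
error rather than returning 0. Dot-plot tables rescale cluster-mean
expression by the *global* min/max over all (cluster, gene) pairs — one
colour scale for the whole panel — and feature tables clamp displayed
values below `min_cutoff=3` without touching stored data. Heat-map
layouts come from average-linkage hierarchical clustering under cosine
distance with optimal leaf ordering (plain dendrogram leaf order is
orientation-ambiguous under ties). The 2×2 chi-square uses the closed form
n(ad − bc)²/(r₁r₂c₁c₂) with 1 df (optional Yates correction, default
off), cross-checked in tests against an independent implementation.

## Synthetic cohort

`default_nanostring_spec()` mirrors the study composition: 444 regular WT
cells, 108 tail cells, 25 control iridophores, 19 control melanocytes
(~600 cells). Five expression programs are planted — eHMP (early
highly-multipotent progenitor: high sox9b/tfap2e/crestin, low-level
co-expression of ltk/mitfa/tfec/pax7b/phox2bb), ltHMP (high ltk, moderate
mitfa/pax7b/phox2bb/neural markers), melanocyte, iridophore (high pnp4a/
alx4, low retained ltk/tfec/foxd3) and xanthophore — over a 46-probe panel
(42 endogenous genes, rpl13, kanamycin, two negative probes). Counts are
negative binomial with mean set by the program and a single global
dispersion (size 8, coefficient of variation ≈ 0.4 at high means);
endogenous entries drop out with probability 0.2; control-class probes
never drop out, keeping reference normalization well-posed. The planted
lineage is eHMP → ltHMP → {M, I}.

`default_taqman_spec()` draws 159 cells over 13 genes plus the two
control assays; Ct = clamp(36 − log2(a + 1), 0, 40) + N(0, 0.25) with
abundance a drawn from the same programs, zero abundance mapping to
Undetermined, and a constant spike-in abundance (near-constant Ct ≈ 24).

What the generator does *not* emulate: amplification-efficiency
differences between assays, probe-specific background, cell-cycle or
stage gradients within a type (types are homogeneous blobs, so pseudotime
recovery is tested at cluster granularity, not within-cluster), doublets,
and batch effects. Passing tests therefore demonstrate correctness of the
pipeline's logic and its behaviour under overdispersion and dropout — not
performance on any real cohort.

## Numerical conventions

- All randomness flows from one master seed; replicate and stage sub-seeds
  are derived via a seed sequence and logged.
- Cosine distance on a zero-norm vector is an error, never NaN.
- qual ties: smaller cluster, then lower id. Marker ties: alphabetical.
  MST ties: smaller weight, then lexicographic cluster pair. Trim ties:
  cell id.
- Cluster labels are relabelled by first occurrence, so output is stable
  under permutation of cell order (up to relabeling).
- The resolution → 0 modularity limit yields a single community on a
  connected SNN graph; disconnected components (e.g. far-separated blobs
  that share no neighbors) remain separate at any positive resolution.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
~600-cell default cohort with the centre-point grid (3 resolutions × 3
replicates); this is the package's reference configuration and completes
in well under a minute per run on a single CPU. The full 189-point default
grid is exposed through the configuration and the CLI's `--full-grid` for
larger studies.

## Known limitations

- The qual score anchors exactly two control sets (melanocytes,
  iridophores); generalizing to k control sets is a documented extension.
- Imputation is a consensus heuristic capturing the contract "impute
  zeros from cluster consensus"; it is not a reimplementation of any
  specific published imputation algorithm.
- tSNE cannot project held-out cells; only UMAP supports the
  fit-on-WT / transform-all workflow.
- Thresholds that published work leaves unstated (cell-signal minimum,
  probe prevalence, norm-factor bounds) are explicit configuration with
  conservative defaults; matching a specific study's exact survivor counts
  may require calibrating them against that study's data.
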