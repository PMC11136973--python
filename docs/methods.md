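# Methods

This note documents the models and procedures implemented in mcatlas,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions that matter for
reproducibility.

## Metacell clustering

Cells are partitioned into metacells — small, transcriptionally
homogeneous clusters treated as the atomic unit of expression
profiling — in six steps.

**Downsampling.** Cells above a target depth (default: the 5th
percentile of per-cell totals) are subsampled without replacement
(multivariate hypergeometric) to exactly that depth, so per-gene
statistics are not confounded by library size. Cells at or below the
target are untouched.

**Feature selection.** A gene is informative when its total UMI count
exceeds 30, it has more than 2 UMIs in at least 3 cells, and it passes
two distribution filters computed on downsampled counts:

- *size correlation* — Pearson correlation of the gene's downsampled
  counts with pre-downsampling per-cell totals; the filter keeps genes
  with correlation strictly below −0.1. On depth-normalized counts this
  statistic is centered near zero for essentially all genes, so the
  filter as stated excludes nearly everything; its semantics in the
  originating framework are not published. It is therefore
  config-disableable, and the high-level `cluster_cells` pipeline runs
  with it off by default while still reporting the statistic per gene.
- *niche score* — the fraction of the gene's downsampled UMIs found in
  its top-5%-expressing cells, minus the uniform expectation k/n for
  the top k of n cells. The score is exactly 0 for a perfectly even
  gene (its attainable minimum), approaches `fraction − 0.05` for large
  n, and approaches 0.95 for a gene confined to a tiny niche. Genes
  with score > 0.01 pass.

**Balanced KNN graph.** Similarity is the Pearson correlation of
log2(1 + downsampled counts) over feature genes. Each cell ranks its 3K
most similar cells; the undirected edge (i, j) survives iff the rank
product r_ij·r_ji ≤ K², with weight 1/(1 + √(r_ij·r_ji)), and each node
keeps at most 2K incident edges, strongest first. K defaults to 100.
Ties in similarity are broken by cell order (stable sort), which keeps
the construction deterministic.

**Bootstrap co-clustering.** 1,000 iterations (default); each samples
⌈0.75·n⌉ cells without replacement, partitions the induced subgraph,
and increments co-cluster counts for co-assigned pairs and co-sample
counts for co-sampled pairs. The partitioning subroutine is seeded
modularity community detection (Leiden, resolution 1) on the weighted
subgraph; the original framework's graph-cover internals are
unpublished, and seeded modularity communities on a balanced KNN graph
are this package's stand-in.

**Partition derivation.** On frequencies f_ij = co-cluster/co-sample,
each cell keeps its K_cc = 30 strongest partners; an edge is dropped
when f_ij < f_max/α for *both* endpoints (α = 2; f_max is each cell's
strongest frequency); the filtered graph is partitioned by seeded
modularity detection; clusters below the minimum size (15 cells; 10 for
subclustering runs, which are the same pipeline re-invoked on a cell
subset) are dissolved by reassigning members to the surviving cluster
with the largest summed frequency, or flagged outliers when none is
connected. Finally, metacells with more than 50 cells and median
UMI/cell below 500 are removed as low-information.

**Layout.** Metacells are spring-embedded (networkx, seeded) on the
between-metacell mean co-clustering frequency graph; cells scatter
around their metacell centroid with seeded jitter.

## Fold-change profiles

Expression of gene g in cluster m is summarized as a regularized
geometric mean on downsampled counts,
`geomean(g,m) = exp(mean over cells of ln(1 + u)) − 1`, and normalized:
`fc(g,m) = (geomean(g,m) + ε) / (median over clusters + ε)` with
ε = 0.1 (small relative to geometric means of expressed genes; prevents
blow-ups on silent genes). With an even number of clusters the median
is the *lower* median (the ⌈n/2⌉-th order statistic) so that fc = 1 is
attained by an actual cluster; the midpoint convention is available as
a config switch. Markers are, per cluster, the genes with fc ≥ 2 sorted
by fc, capped at 30; heatmap row order follows each gene's argmax
cluster. Annotation scores a cluster against a marker signature as the
mean log2 fc over the signature's genes, assigning the argmax type when
the score clears a floor; exact ties go to the lexicographically first
type label and are flagged.

## Regulatory-region assignment

Peaks come in as 10-column narrowPeak (0-based half-open; −log10 q in
column 9, summit offset in column 10). Records at −log10(q) ≥ 6 are
retained, re-centered to [summit − 125, summit + 125) (250 bp), clipped
at chromosome bounds with a truncation flag, and merged into a
non-overlapping set (a merged record keeps the summit and statistics of
its best-supported member). Promoters are strand-aware windows
[TSS − 50, TSS + 200) on + (mirrored on −); the orientation of the
50/200 pair is ambiguous in common shorthand, so the swapped reading is
a config switch. External intervals (e.g. H3K4me3 peaks) overlapping a
window are unioned in.

Assignment rules, applied per peak: (1) a peak overlapping exactly one
gene's promoter links to that gene only, promoter-flagged; several
promoters → the nearest TSS wins (ties to the smaller gene id), flagged
ambiguous. (2) Otherwise the peak links to every gene with
|summit − TSS| ≤ 20,000 whose TSS is not separated from the summit by
another gene's TSS strictly in between ("beyond a more proximal gene");
genes on both sides may link simultaneously. Distances are measured
summit-to-TSS because the summit anchors the 250 bp standardization.
An exhaustive brute-force implementation of these rules doubles as a
test oracle; the production implementation reduces them to
nearest-TSS-per-side plus the promoter override.

Cell-type region sets use the maximum FC among a region's assigned
genes in that type: ≥ 1.5 high, [1.1, 1.5) mild, ≤ 1 background, with
precedence high > mild > background keeping sets disjoint; FC in
(1.0, 1.1) falls in no set.

## Motif toolkit

Per-column information content is IC_j = 2 + Σ_b p_jb log2 p_jb bits
(uniform background; 0·log 0 = 0). The curation filter keeps motifs
with a run of ≥ 4 consecutive columns at IC ≥ 0.5, or ≥ 2 disjoint runs
of ≥ 3 such columns. Similarity between two PPMs is the maximum, over
all alignments with ≥ 6 bp overlap and over the reverse complement, of
the weighted Pearson correlation of flattened aligned columns; each
aligned column pair is weighted by the mean of the two columns' IC (the
weighting scheme of the reference merge procedure is named but not
defined, so mean aligned-column IC is this package's choice). Pairs
with no admissible alignment score −1 and never merge. Redundancy
reduction is average-linkage hierarchical clustering on 1 − similarity
cut at 0.05 (i.e. average similarity ≥ 0.95), keeping the member with
the highest total IC (ties lexicographic).

Scanning scores both strands with log2-odds against a uniform
background with a 10⁻³ probability floor (prevents −∞; the reference
scanner's settings are unpublished). Windows containing N never score.
A hit requires score > 0.8 × the motif's maximum achievable score;
"best only" keeps one hit per region per motif (leftmost, then +
strand).

Enrichment: foreground region sets (per cell type and FC bin) are
compared against 2× GC/length-matched backgrounds sampled from the
genome excluding foreground overlap, with foreground regions split into
10 equal-size GC bins and backgrounds matched per bin (the GC window
relaxes stepwise, with a warning, if a bin is unsatisfiable). Per
(cell type, bin, motif): k of n foreground regions have ≥ 1 hit;
p₀ = (background hits + 0.5)/(n_bg + 1); the one-sided binomial tail
P(X ≥ k | n, p₀) gives the p-value and
log2FC = log2(((k + 0.5)/(n + 1))/p₀) the effect size (0.5/1
pseudocounts avoid degenerate zeros); Benjamini-Hochberg runs across
motifs within each (cell type, bin), matching the per-bin testing unit.
Per-region empirical p-values are rank-based within the region's GC
bin: p = (1 + #background best scores ≥ observed)/(1 + n_background).

## Cross-species comparison

Marker statistics per (gene, cell type): expression normalized per cell
to 10,000 total; one-sided rank-sum test of the type's cells against
all others — exact enumeration of rank assignments when both groups
have ≤ 10 tie-free observations, tie-corrected normal approximation
with continuity correction otherwise (exactness where enumeration is
cheap); FC = (mean + 0.1)/(mean rest + 0.1), mirroring the profile
regularization; BH across genes within each type. Shared features
between two species' cell types are orthology groups with at least one
gene passing (adjusted p < 0.05, FC ≥ 1; TFs FC > 1.25) in each
species' type. Cell-type correlation collapses each orthology group to
one meta-gene per species (mean FC over members, avoiding
double-counting of expanded families), keeps groups with FC > 1.05 in
at least one cell type of either species (the "either species" reading
of an underdetermined convention; config-exposed), and reports Pearson
coefficients per cell-type pair plus row-wise best matches; pairs with
fewer than 3 usable groups are reported missing.

## The simulator

`mcatlas.synth` emulates the data-generating process the pipeline
assumes, not any particular organism:

- **Expression**: a shared symmetric-Dirichlet baseline over genes
  (concentration 1 — the simplest exchangeable null); per type,
  disjoint marker genes raised by a planted fold, with non-marker genes
  rescaled per type so program columns sum to one while marker
  between-type ratios stay exactly at the planted fold. Cells draw
  counts multinomially at depths from a log-normal law (median 1,000
  UMIs/cell, σ = 0.6, truncated to [200, 20,000]) emulating shallow
  plate-based depths.
- **Genome**: i.i.d. bases at a target GC, TSSs spaced ≥ a minimum with
  a gene-free tail so gene-distal regions exist; peaks placed at
  sampled TSS offsets (default ±2 kb) with summits at midpoints, plus
  orphan peaks ≥ 20 kb from every TSS; true assignments recorded by
  construction.
- **Motifs**: sharp random PPMs (per-column dominant base ~0.85–0.97
  with uneven residual mass, giving non-degenerate log-odds scores);
  instances sampled column-wise from the PPM are written over reference
  bases (coordinates of peaks and TSSs are preserved) inside target
  peaks with probability fg_rate and elsewhere with bg_rate, all
  logged. Distinct "families" for redundancy-reduction experiments are
  drawn with mutually distinct consensi (no shared 6-mer on either
  strand) and varied by probability perturbation, one-column shifts,
  and reverse complementation.
- **Species pair**: each gene is duplicated in species B, mapped 1:1,
  or lost; conserved types inherit A's programs through the orthology
  map (split equally among duplicates) with multiplicative log-normal
  noise; non-conserved types get fresh baselines sharing no planted
  markers.

What the simulator does *not* emulate: ambient RNA, doublets,
batch/plate effects, sequencing error, overdispersion beyond
multinomial sampling, realistic genome composition (repeats, CpG
islands, chromatin domains), correlated gene programs, or peak-calling
noise. Passing recovery tests therefore demonstrates the correctness
and calibration of the algorithms under their own model assumptions,
not robustness to every artifact of real data.

All randomness flows from a single integer seed through named
substreams per operation, so each component is reproducible in
isolation and identical seeds give byte-identical outputs.

## Evaluation experiments and problem sizes

`mcatlas.evaluate` packages the recovery experiments; the test suite
and `scripts/acceptance.py` run them at desk scale, chosen to finish in
minutes on one CPU while keeping the statistics stable:

- clustering recovery: 8 types × 375 cells (3,000 cells), 2,000 genes,
  20 markers/type at fold 8, median depth 1,000; 30 bootstrap
  iterations (recovery is insensitive to raising this toward the
  analysis default of 1,000, at proportional cost); success is
  metacell-majority ARI ≥ 0.85.
- fold-change and peak-assignment oracles: direct-formula and
  exhaustive-rule re-implementations on hundreds of random small
  instances, exact agreement (1e-10 / identical link sets).
- motif dedupe: 6 families × 5 copies, exact collapse to 6.
- enrichment: 200 foreground regions, fg 0.4 vs bg 0.05, adjusted
  p < 0.01 and log2FC ≥ 1; type-I control on a non-planted motif across
  null runs.
- empirical-p calibration: 1,000 null regions, fraction below 0.05
  within [0.03, 0.07].
- cross-species: 6 types, divergence noise 0.1, all conserved pairs
  best-matched.

## Known limitations

- The size-correlation and niche-score statistics, the α-filter
  semantics, and the bootstrap partitioning subroutine stand in for
  unpublished internals of the original clustering framework; they are
  flagged in config and the recovery experiments do not depend on the
  size-correlation filter.
- Hit scores of near-uniform motifs (maximum log-odds ≤ 0) are not
  scannable and such motifs are skipped with a warning.
- The background sampler requires enough non-foreground genome per GC
  bin; on small or foreground-saturated genomes it relaxes the GC match
  stepwise rather than failing silently.
- `rank_markers` densifies the count matrix; it is intended for
  cell-type-level comparisons (thousands of cells), not
  atlas-scale matrices with hundreds of thousands of cells.
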