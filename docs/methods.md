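# Methods

## Data model

A poly(A) site is a single 1-based, strand-aware genomic position — the
cleavage point reported by an upstream site caller. The `PACDataset` couples
a non-negative integer count matrix (sites × observations) with a site table
(chrom, strand, coord, and after annotation gene_id/region) and an
observation table (group label per cell or sample). Counts are stored sparse
(CSR) internally; the API contract is value-level, so dense or sparse input
is indistinguishable to callers. Observations without a group label are
rejected at read time because every downstream operation is group-aware.
On-disk layouts are MatrixMarket + `sites.tsv`/`obs.tsv` sidecars or a single
dense TSV; writing uses an integer MatrixMarket field and plain
tab-separated UTF-8 so that read(write(x)) is bit-exact.

## Site annotation

`load_annotation` reduces a GTF/GFF3 to one merged model per gene: exons are
the union over transcripts, introns the within-gene gaps between merged
exons. 3'UTRs come from explicit `three_prime_utr` records when present;
otherwise they are derived per transcript as the exonic bases strictly 3' of
the CDS stop, then unioned. Merging is gene-level rather than
transcript-resolved because sites are gene-level points and the browser-style
figure draws one merged model.

`annotate_sites` assigns each site the region with priority
`UTR3 > ext_UTR3 > exon > intron > intergenic`, matching strand. The
extended 3'UTR is the `ext3utr` bp window immediately downstream of a gene's
3' end (default 1000 bp, a common allowance for unannotated distal sites),
minus any base covered by another same-strand gene. When two same-strand
genes compete at equal priority the site goes to the gene with the nearer 3'
end, then to the lexicographically smaller gene_id — an arbitrary but
deterministic tie-break. Lookup uses one interval tree per
(chromosome, strand); the test suite checks equivalence against a quadratic
all-pairs oracle on random instances up to 10^3 sites × 10^2 genes.
Annotation is idempotent and leaves counts untouched.

## RUD (Relative Usage of Distal poly(A) site)

For gene *g* and observation *o*, usable sites are those annotated
`UTR3` or `ext_UTR3`; genes need at least two. The distal site is the usable
site farthest 3' in strand-aware order (highest coordinate on `+`, lowest on
`-`), and

    RUD(g, o) = count(distal) / count(all usable sites of g in o).

For genes with more than two sites the denominator is the sum over all
usable sites: this keeps RUD in [0, 1], reduces to the standard two-site
definition, and makes proximal usage exactly 1 − RUD for two-site genes. The
value is missing when the denominator is below `min_counts` (default 5 — a
floor against single-cell sparsity; with fewer reads a usage ratio is mostly
sampling noise). No smoothing or imputation is applied; missing stays
missing so downstream statistics see the real support. RUD is invariant to
per-cell scaling of counts and monotone in the distal count.

## Marker detection

For an ordered pair of groups (X, Y), every gene with at least `min_cells`
(default 10) non-missing RUD values in both groups is tested with a
two-sided Wilcoxon rank-sum test on the per-cell RUD values — the standard
distribution-free choice for per-cell single-cell comparisons. With ≤ 25
cells per group and tie-free values, the p-value comes from the exact
permutation null of the Mann–Whitney U statistic, computed by a
dynamic-programming recursion over rank subsets
(p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1); otherwise the normal
approximation with tie and continuity correction is used. Two identical
constant samples are assigned p = 1 directly. Benjamini–Hochberg adjustment
is applied within each pairwise comparison (not across comparisons), so
per-pair marker counts are directly comparable. Markers satisfy
q ≤ `alpha` (default 0.05) and |ΔRUD| ≥ `min_delta` (default 0.1);
direction is *positive* when mean RUD is higher in X. Swapping X and Y flips
direction and the sign of ΔRUD but not p, so the positive set of (X, Y)
equals the negative set of (Y, X). `count_markers_pairwise` reports each
unordered pair once, earlier group first in the supplied group order.

## Embeddings

`compute_embedding` embeds observations with UMAP (defaults n_neighbors 15,
min_dist 0.1, seed 42, all recorded in the result). Site-expression input is
normalized per cell to 10k counts, log1p-transformed, and reduced to 50
principal components before the neighbor graph — standard single-cell
practice that stabilizes the metric. RUD input is median-imputed per gene
(neutral 0.5 where a gene is missing everywhere) for the embedding only; the
RUDMatrix itself is never modified. Exactly duplicated observations are
collapsed before the fit and mapped back to identical coordinates, which
makes duplicate consistency a hard guarantee rather than an accident of the
optimizer. With a fixed seed the result is reproducible on one platform.

## Figures

Every figure is assembled as an inspectable spec object (track list, mark
coordinates, axis limits, panel counts) and then rasterized with matplotlib;
tests assert on the spec because pixel comparisons are brittle. The track
figure shares one genomic x-axis across the merged gene model, the pA track
(mark height ∝ pseudo-bulk expression), one coverage track per group, and a
sites × cells heatmap with cells ordered by group then total gene count
descending. Coverage counts reference-consuming aligned bases (CIGAR M, D,
=, X; N skips) of reads overlapping the region, unstranded by default with
an optional same-as-gene strand filter. The bubble chart is the dot chart
with size/color encodings swapped. Plot functions never mutate their inputs;
PNG vs PDF follows the output extension.

## Simulator

The generator emulates a multi-stage single-cell 3'-end dataset. Genes are
laid on a toy genome (100 genes per chromosome, 10 kb spacing, 2 kb span,
alternating strands, two exons with the 3'UTR in the 3'-terminal exon), each
with a proximal and a distal site 200 bp apart inside the 3'UTR. Per cell,
the gene total is negative binomial with mean `depth_mean` and variance
μ + μ²/dispersion; the distal count is binomial given the group's true RUD.
Shifted genes move linearly from `base_rud` by `shift_direction · delta_rud`
across the group order (downward by default — progressive 3'UTR shortening).
Defaults: 3 groups × 100 cells, 200 genes, frac_shifted 0.3, delta_rud 0.4,
depth_mean 10, seed 42 (the `strong` preset); `base_rud` 0.8 reflects a high
baseline distal usage before shortening and `dispersion` 2 a typical
scRNA-seq overdispersion. The `null` preset (2 groups × 50 cells, no shift)
supports type-I-error checks. All randomness flows from a single
`numpy.random.default_rng(seed)`.

What the simulator does *not* emulate: genes with more than two sites
(exercised with hand-built fixtures instead), ambient contamination,
doublets, batch effects, group-specific total expression, or realistic gene
models (single-isoform, fixed geometry). Passing tests therefore demonstrate
correctness of the computations and calibration under a clean binomial
sampling model, not robustness to those real-data artifacts.

A note on the embedding checks: because the simulator plants group structure
only in usage proportions (totals are group-invariant by design), the
label-recovery check runs on the RUD-usage embedding, where the planted
stages separate fully; the site-expression embedding of the same data keeps
the stages separable in PC space but blurs centroid geometry in the 2D
layout of what is, by construction, a usage continuum.

## Problem sizes and numerical choices

The validation suite uses desk-scale instances chosen to exercise every code
path: 20 random annotation instances up to 1000 sites × 100 genes against
the brute-force oracle; exhaustive rank enumeration for group sizes 2–6;
100 null replicates (200 genes, 2 × 50 cells) for the type-I check, which
lands around 10⁻⁴ mean fraction at q ≤ 0.05; the strong preset for power
(100% of 60 planted genes at q ≤ 0.05, min_delta 0.1) and embedding recovery
(100% nearest-centroid). Ties in the rank-sum test always route to the
corrected normal approximation; degenerate all-equal samples short-circuit
to p = 1. Empty datasets, exonless genes, unknown chromosomes, and empty
regions are handled explicitly (empty outputs plus a warning rather than
errors). Seeds derived from a user seed are kept below 2³¹.

## Known limitations

- Region priority order and the 1000 bp extended-3'UTR default are package
  decisions; tools differ on both, so absolute region tallies are not
  comparable across toolkits without aligning these choices.
- RUD with >2 sites (distal vs all) is one of several conventions in use
  (distal-vs-proximal-only is another); comparisons across tools should
  check the convention.
- Marker detection tests usage only; it will not flag genes whose APA change
  is confined to expression level at constant usage.
- No BigWig input, no interactive display, no peak calling from raw reads —
  site identification belongs upstream.
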