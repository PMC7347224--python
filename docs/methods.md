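# Methods

## The two-layer figure model

Every figure in this package is a pair of layers over one coordinate system:

- a **background** holding an aggregate of the *full* dataset — a hexagon
  binning of all genes (or all gene–replicate combination points), a raw
  point cloud, or per-axis five-number-summary boxes — with hover metadata
  attached to every geom (a hexagon's gene count, a point's gene name);
- a **foreground** holding a *subset* overlay — DEG points, one gene's
  replicate combinations, cluster polylines — with hover gene names and a
  style (point size, alpha, color).

The background is the expensive part: for a litre plot over G genes with m
and n replicates it aggregates G·m·n points. The engine therefore builds a
background at most once per (data, geom, parameters) key: keys are SHA-256
digests of the input points and parameters, backgrounds are cached on a
`LayerSession`, and the session's `build_log` counts actual constructions.
Replacing the foreground (`update_foreground`) produces a new figure object
that shares the background by identity; any number of foreground updates
leaves `build_log` at 1 and the background section of the serialized payload
byte-identical.

"Redrawing" is operationalized as payload recomputation. The unit of output
is a canonical JSON payload document (sorted keys, compact separators) with
`axes`, `background` and `foreground` sections; the background digest is the
redraw detector used throughout the tests. Rendering that payload — to a
static PNG via matplotlib, or to a small self-contained HTML/SVG viewer with
hover titles — is a separate export step and never feeds back into layer
data; zoom and pan are likewise rendering-level concerns.

## Input model

Counts enter as a gene × sample table of nonnegative reals (integers are not
required, so CPM-style normalized matrices are valid). Sample labels encode
the design as `TREATMENT.REPLICATE`, split at the *last* dot so treatment
names may themselves contain dots; replicate indices are any unique integers.
At least two treatments are required. Per-contrast DE metrics (`logFC`,
`PValue`, `FDR`, plus arbitrary extra numeric columns) bind to one unordered
treatment pair; `PValue`/`FDR` must lie in [0, 1], all values must be finite,
and metric gene ids must be a subset of the matrix's. Gene lists are plain
text, one id per line; an unresolvable id in a user list raises an error
rather than being dropped, because a silent drop hides typos in overlays.

## Hexagonal binning

The lattice is the classic dual-offset (Carr) construction: hexagon centers
form two interleaved rectangular lattices, the second offset by half a
spacing in x and y, and each point goes to the nearest center under a
Euclidean distance scaled by `(hex_width, hex_height)`. `n_bins` counts
hexagon columns across the x-range (the single "hexagon size" control);
`hex_width = span(x)/n_bins` exactly, and
`hex_height = hex_width · (span(y)/span(x)) · √3`, which renders regular
pointy-top hexagons when the two ranges are displayed at equal size. Ranges
pad the data extent by 5% per side by default; a degenerate extent (all
values equal) expands to a unit interval centered on the data.

Numerical choices: nearest center within one rectangular sublattice is
per-coordinate rounding, so only two candidates are ever compared; exact
half-way points within a sublattice round *down* (`ceil(t − 0.5)`), and ties
between the two sublattices break toward the lexicographically smaller
(center_x, center_y) — both rules make assignment fully deterministic.
Every bin stores its member point ids, so membership (hover counts, click
overlays) is exact rather than re-derived; empty bins are not stored. The
bin equality of any other hexbin implementation is *not* claimed — lattice
anchoring and tie rules differ across tools — only internal exactness, which
the tests verify against exhaustive nearest-center search.

## Plot builders

**Scatterplot matrix.** n samples give n² panels: label-only diagonals and,
for each ordered pair (row, col), a hexbin of (count in col, count in row)
over all genes. Each panel bins its own extent (a shared grid would distort
sparse panels). Clicking a hexagon overlays its member genes in *every*
panel at that panel's own coordinates; the click targets the background
layer only. An optional log2(count+1) axis transform exists and is off by
default.

**Litre plot.** For a treatment pair, every gene contributes one background
point per between-treatment replicate combination (first treatment on x,
second on y); within-treatment pairs are excluded because the plot's purpose
is treatment-vs-treatment variability. Genes are toured one at a time in
metric order (e.g. FDR ascending), ties broken by gene id; each step
replaces the previous overlay with the next gene's m·n points. Stepping past
the last gene raises a dedicated exhaustion signal and leaves the figure
unchanged.

**Volcano plot.** x is log2 fold change, y is −log10 of the chosen
significance column (PValue by default, FDR selectable). A significance of
exactly 0 is clipped to the smallest positive normal double (≈2.2e−308)
before the log so the most significant genes keep finite, top-ranked y; the
hexbin is computed in the clipped display space. The overlay is exactly the
intersection of the |logFC| ≥ lfc_min and sig ≤ sig_max filters, so relaxing
either threshold can only add genes.

**Parallel coordinates.** Samples sit at integer x-positions 1..n in design
order. Profiles are standardized per gene by (value − mean)/sd with the n−1
denominator; constant rows map to zeros and are flagged rather than divided
by zero. The background is the per-axis five-number summary of the full
dataset (quartiles by linear interpolation of order statistics at
1 + p·(n−1), one documented convention testable against a sorting oracle).

## Consecutive box selection

A gene survives a query rectangle [x1,x2] × [y1,y2] iff its piecewise-linear
polyline satisfies y1 ≤ f(x) ≤ y2 for **every** x in [x1,x2] ∩ [1,n] — the
continuous predicate, not the vertex-only selection some plotting toolkits
apply (the two coincide only when boxes span whole axes). Because f is
piecewise linear, its extrema on an interval occur at contained axis
vertices or the interval endpoints, so the predicate is evaluated exactly
from finitely many values (vertex-and-endpoint criterion). A query whose
x-range misses every axis retains all genes — the universal quantifier is
vacuous — and logs a warning, since it is usually a mis-drawn box.
Consecutive queries intersect; the result preserves profile order.

## Hierarchical clustering

Agglomeration runs on Euclidean distances between standardized profiles
(standardization is the default and exposed as a flag) via the
Lance–Williams recurrence, with the full method menu: `ward.D` (default),
`ward.D2`, `single`, `complete`, `average`, `mcquitty` (WPGMA), `median`
(WPGMC), `centroid` (UPGMC). `ward.D` applies the Ward update to the
supplied distances as given; `ward.D2`, `median` and `centroid` update
squared distances and report square-rooted heights. Ties between
equal-distance merges break toward the lexicographically smallest
(older id, newer id) pair, making trees deterministic; `median`/`centroid`
may produce height inversions, as is inherent to those methods. Cutting at
k undoes the last k−1 merges and numbers clusters by first appearance among
the leaves.

Overlay approaches: (1) cluster only a user subset and overlay it;
(2) cluster the full dataset, overlay only the subset colored by its
full-data cluster; (3) cluster and overlay everything. Every per-cluster
parallel-coordinate figure keeps the *full* dataset's five-number-summary
underlay, and cluster colors come from one fixed ordered palette shared by
all plot builders, so cluster 3 is the same color in a PCP, a scatterplot
matrix, a litre plot and a volcano plot. Cluster memberships export as one
plain-text file per cluster.

## Synthetic data generator

The simulator emulates a bulk RNA-seq count matrix: per-gene baseline means
are lognormal around a median of 50 reads (σ_log = 1, a realistic spread of
expression levels), counts are negative-binomial with gene-shared dispersion
α = 0.2 (Var = μ + αμ², typical of bulk experiments), and a planted fraction
of DEGs (default 10%) differ between the first two treatments by a factor of
2^lfc (default lfc = 2), applied symmetrically (±lfc/2) with half the DEGs
up- and half down-regulated. Identical configuration and seed give
byte-identical output.

The companion `compute_metrics` is a transparent stand-in for a DE pipeline:
logFC as a difference of log2 means with pseudocount 1 (difference of logs,
not log of a ratio, so swapping the pair negates it bit-for-bit), Welch's
t-test on log2(count+1) when both groups have ≥ 2 replicates, and
Benjamini–Hochberg FDR across genes (zero-variance/equal-mean genes get
p = 1). It is deliberately *non-canonical*: real analyses should import
metrics from an established caller (edgeR, DESeq2, limma); this stand-in
only supplies the columns such a pipeline would.

What the generator does not model: library-size differences and
normalization, gene-specific dispersion, correlated genes, batch effects,
and outlier samples. Passing tests therefore demonstrate the correctness of
the layering, binning, selection and clustering machinery on realistic count
magnitudes — not robustness of any DE inference to those real-data
complications, which this package does not perform.

There is also a fixed 8-gene × (2 treatments × 2 replicates) worked fixture
whose counts are hand-chosen so every pseudocount-1 logFC is an exact small
integer, used for exact-value tests and the README example.

## Problem sizes and defaults

The heaviest routine exercise is a 10,000-gene litre background (60,000
points, 2 vs 3 replicates) followed by 50 foreground updates; it runs in
seconds. Oracle comparisons use 8-point clustering fixtures over 20 seeds,
20 random hexbin point sets up to n = 500, 200 standardized profiles × 100
random box queries, and 10 simulator seeds at 1000 genes × 5 replicates —
sizes chosen so exhaustive oracles stay exact and the whole suite runs in a
few seconds. Defaults throughout: `n_bins` 10, pad fraction 0.05,
pseudocount 1, point size 2, polyline alpha 0.6, clustering method `ward.D`.

## Known limitations

- No claim of bin-identity with any other hexbin implementation (see above).
- Clustering is O(n³) worst case in the number of clustered genes; it is
  meant for the subset/cluster-overlay workflows, not for clustering
  hundreds of thousands of genes.
- The HTML export is a minimal viewer (hover titles only); it does not
  implement in-browser box selection or gene stepping — those are library
  and CLI operations whose outputs are the payload and gene-list files.
- p-values require ≥ 2 replicates per group; with single replicates only
  fold changes are produced.
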