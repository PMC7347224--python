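# layervis

Two-layer figures for RNA-seq count data: expensive background aggregates
(hexagon binnings of *all* genes) are computed once and cached, while
foreground overlays (DEG subsets, single genes, clusters) are replaced freely
and never trigger a background rebuild.

## Who this is for

Researchers exploring a gene × sample read-count matrix — the value at row
*i*, column *j* is the number of reads assigned to gene *i* in sample *j*,
the same input as DESeq2/edgeR/limma — together with per-contrast
differential-expression metrics (log₂ fold change, p-value, FDR) from their
favorite DE pipeline. Typical questions: how does one candidate DEG's
replicate-to-replicate variability compare to the whole dataset? Which genes
pass a fold-change/significance threshold, and where do they sit? Which
expression profiles co-cluster, and do the called DEGs follow them?

## The model

A figure is `background + foreground`:

- **background** — a hexagonal binning (dual-offset Carr lattice,
  nearest-center assignment, deterministic tie-breaks) of all genes, with
  *exact* per-hexagon membership, so hovering a hexagon reports its gene
  count and clicking it recovers exactly its member genes; or a point cloud;
  or per-axis five-number-summary boxes.
- **foreground** — overlay points or polylines for a gene subset, with hover
  gene names and adjustable style.

Backgrounds are cached per (data, geometry, parameters) digest on a session;
the session's build log proves a background was constructed exactly once no
matter how many overlays follow. The figure serializes to a canonical JSON
payload whose background section is byte-identical across foreground
updates — that payload is the unit of output (PNG/HTML rendering is a thin
export layer on top).

Plot builders: all-pairwise-samples **scatterplot matrices** (n samples → n²
panels, click-to-overlay-everywhere), **litre plots** (all G·m·n
between-treatment replicate combinations collapsed onto one plane, one gene
overlaid at a time in metric order), **volcano plots** (log₂FC vs −log₁₀
significance with threshold-driven overlays), and **parallel coordinates**
with the continuous consecutive-box-selection predicate (a gene survives a
box [x₁,x₂]×[y₁,y₂] iff its polyline stays inside the band over the *whole*
x-interval) and agglomerative-clustering overlays (hclust-style method menu,
`ward.D` default). See `docs/methods.md` for the full model description.

## Worked example

The built-in worked fixture is an 8-gene, 2-treatment × 2-replicate matrix
whose counts were chosen so every pseudocount-1 log₂ fold change is an exact
integer (w1: +1, w2: −1, w3: 0, w4: +2, w5: −2, w6: +3, w7: −3, w8: +5).

```python
import layervis as lv
from layervis import volcano, litre

matrix, metrics = lv.worked_fixture()
print("matrix:", matrix.n_genes, "genes x", matrix.n_samples, "samples")

fig = volcano.build_volcano_background(metrics, n_bins=6)
fig = volcano.threshold_overlay(fig, metrics, lfc_min=1.0, sig_max=0.05)
print("overlaid genes:", list(fig.foreground.gene_ids))

it = litre.order_genes(metrics, "FDR", "increasing")
lfig = litre.build_litre_background(matrix, lv.TreatmentPair("A", "B"), n_bins=5)
print("litre background points:", lfig.background.payload.total_count)
lfig, it = litre.plot_next_gene(lfig, it, matrix)
print("first gene overlaid:", sorted(set(lfig.foreground.hover.values())))
print("background builds:", lfig.build_count)
```

prints

```
matrix: 8 genes x 4 samples
overlaid genes: ['w1', 'w4', 'w5', 'w6', 'w7', 'w8']
litre background points: 32
first gene overlaid: ['w6']
background builds: 1
```

The volcano overlay is every gene with |log₂FC| ≥ 1 *and* p ≤ 0.05 — six of
the eight (w2 and w3 miss the significance cut). The litre background holds
8 genes × 2 × 2 replicate combinations = 32 points; the first stepped gene is
w6, the fixture's lowest-FDR gene (ties broken alphabetically), and the
background was built exactly once despite the overlay.

From the shell, the same workflows run as subcommands — `validate`,
`simulate`, `scatmat`, `litre`, `volcano`, `pcp`, `cluster` — for example:

```sh
layervis simulate --genes 500 --reps 3 --seed 1 --out demo
layervis volcano --metrics demo/metrics_A_B.tsv --nbins 9 --lfc 1 --sig 0.05 \
    --out demo/volcano --png --html
layervis cluster --counts demo/counts.tsv --k 4 --approach 3 --verbose \
    --out demo/clusters
```

Each run writes payload JSON, any produced gene lists as plain text, and a
`manifest.json` with SHA-256 digests of every artifact; runs with the same
config and seed are byte-identical.

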