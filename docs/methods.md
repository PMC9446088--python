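# Methods

## The model

`tessella` treats spatial domain detection in sequencing-based spatial
transcriptomics (ST) as an image-analysis problem.  Most spatial clustering
tools assume that neighboring barcodes are transcriptionally similar; that
assumption breaks in tissues where one anatomical territory mixes several
cell types (a hippocampal field, a cortical column).  Representing each
barcode's whole transcriptome as a *color* and the assay as an *image*
sidesteps it: blurring an image averages colors over space, so a territory
composed of several interleaved cell types converges to a characteristic
mixed color that segmentation can find, even though no two neighboring
barcodes look alike.

The pipeline, in execution order:

1. **Preprocessing.** Counts are library-size normalized to a scale factor
   of 10,000 and log1p-transformed.  The 2,000 most variable genes are kept;
   the variability statistic is the variance of standardized expression,
   where each gene is scaled by an expected standard deviation taken from a
   robust mean-variance trend (running median of gene variances over ~20
   mean-quantile bins) and standardized values are clipped at
   `sqrt(n_barcodes)`.  The trend median is deliberately robust: a lowess
   fit lets a hypervariable gene inflate its own expectation when gene means
   are homogeneous, which suppresses exactly the genes the statistic should
   rank first.  Genes are then z-scored (clipped at ±10) and reduced to 30
   principal components.
2. **Color embedding.** A 3-D UMAP of the PC scores is computed
   (`n_neighbors=15`, `min_dist=0.1`, fixed seed, single-threaded for
   determinism), each axis is min-max normalized to [0, 1] and read as one
   of R, G, B.  A constant axis maps to zeros rather than NaN.  Duplicate
   score rows are collapsed before UMAP so identical transcriptomes are
   guaranteed identical colors.  Alternatively a slice of three PCs feeds
   the channels directly: each channel is the absolute score of the barcode
   on its PC — the summed magnitude of the loading contributions to that
   component — min-max normalized.  The score-magnitude reading was chosen
   because loadings are per-gene quantities; the alternative reading
   (summing |loading x expression| over genes) gives a gene-weighted variant
   of the same quantity and is not implemented.
3. **Image building.** Barcodes in low-density sections of a 50x50 grid
   over the bounding box (below the 0.01 quantile of nonzero section
   occupancies) are dropped as strays.  Note that the stray filter is only
   guaranteed idempotent when removal leaves the bounding box unchanged;
   edge strays shrink the box and re-bin the grid.  Remaining coordinates
   are mapped affinely (aspect-preserving, y flipped once) onto a canvas
   with ~1,000 pixels on the longer side, and each in-bounds pixel is
   assigned to its nearest barcode — a discrete Voronoi tessellation
   computed by nearest-site labeling, which at pixel resolution equals
   polygon clipping and is directly checkable against a brute-force oracle.
   Exact distance ties break to the lowest barcode index.  Every barcode
   owns at least its center pixel (rounded position; collisions shift to
   the nearest free pixel).  Nearest-neighbor resizing retains all barcodes
   the same way.
4. **Segmentation.** Optionally the color histogram is balanced per channel
   (empirical-CDF mapping rescaled to span [0, 1]; constant channels are
   left untouched), then for each k in a user-chosen sequence the image is
   smoothed (Gaussian / median / box, optionally TV-regularized) and colors
   are clustered by k-means (k-means++ with 10 restarts, fixed seed).  By
   default only center-pixel colors are clustered — one observation per
   barcode; the all-pixel mode is sharper in homogeneous tissue but noisier
   in mixed tissue.  After each round every tile is repainted with its
   cluster's mean color, so a decreasing k sequence contracts the color
   space monotonically.  k is the granularity knob, playing the role that
   resolution plays in Louvain/Leiden clustering.
5. **Territory isolation.** The capture radius is a proportion (default
   0.05) of the maximum pairwise barcode distance in assay coordinates (the
   diameter is found on the convex hull).  Within each color cluster,
   territories are connected components of the graph joining barcodes at
   distance <= radius — exactly single-linkage clustering cut at the
   radius, which the tests verify against a brute-force BFS oracle.
   Components under 50 barcodes are pooled into an `isolated` group; an
   optional, off-by-default rule also isolates components whose nearest
   other component lies beyond the capture radius.  Surviving territories
   are renumbered 1..T by decreasing size (ties by smallest barcode index).
6. **Morphology.** A territory's tile mask is dilated/eroded by a sequence
   of signed pixel steps with a square (Chebyshev-ball) structuring
   element; `[-5, 5]` is an opening (cleaning), `[5, -5]` a closing
   (filling — no dedicated flood fill exists; closing is the filling
   operator).  The new territory is the set of barcodes whose center pixel
   lies in the final mask.
7. **Layering.** The territory mask is binarized, X-Y Sobel gradient
   magnitude is computed with edge-replication padding, and barcodes owning
   any nonzero-gradient mask pixel become the next concentric layer, then
   are removed; repetition peels the territory edge-to-core.  If no edge
   pixel is detectable (mask fills the canvas) all remaining barcodes form
   the final layer, which guarantees termination.  Raw layers can be merged
   outermost-first into groups of near-equal raw-layer count.
8. **Differential expression.** Genes must be detected in strictly more
   than 10% of barcodes in at least one group and carry
   |logFC| >= 0.25, where logFC = ln(mean(expm1(x1)) + 1) −
   ln(mean(expm1(x2)) + 1) on log-normalized values (the convention of the
   standard single-cell toolkits, applied to up- and down-regulation
   alike).  Surviving genes get a two-sided Wilcoxon rank-sum test — exact
   enumeration when both groups have <= 8 tie-free observations, otherwise
   the normal approximation with mid-ranks, tie and continuity corrections
   — and Bonferroni correction over the genes actually tested.  Group
   pairs come in five modes (territory vs rest, territory vs each,
   set vs set, cells-of-a-type between territory sets with a >30-cells-
   per-side floor, layer vs layer).

## Simulator

The generator emulates a high-resolution ST puck: 6,000 barcodes uniform on
the unit square, each carrying one cell type's expression.  Cell types come
from a pool of 13 synthetic profiles (the size of a deconvolved Slide-seq
hippocampus type set): 2,000 genes, negative binomial with dispersion 2,
baseline mean 0.5, and per type a disjoint block of 50 marker genes at
5-fold elevated mean.  Ground truth territories are three equal vertical
bands (the shape of "equally sized" territories is not otherwise
constrained; a fixed shape makes truth exact), or for the dotted regime a
background plus five disks with centers on randomly chosen barcodes and
radii uniform in [0.05, 0.25] of the square side, later disks overwriting
earlier ones.

Regime-specific type placement: *pure* — one pool type per territory,
sampled without replacement; *uniform* — each territory a different random
set of `n_types` types in equal proportion; *exponential* — one shared set
of `n_types` types in proportions `P_l = e^l / Σ e^l`, with the proportion
vector cyclically shifted between territories.  The shift (rather than an
independent random permutation per territory) guarantees each territory a
different dominant type; independent permutations would leave two of three
territories sharing a dominant type about 78% of the time, making them
indistinguishable in expectation, which is not the intended benchmark
condition.  *dotted* — every territory (background included) holds 1–3
types in equal mixture.

What the simulator does **not** emulate: bead-size optics, spatially varying
capture efficiency, doublet beads, segmentation-free sub-cellular spots, or
realistic gene-gene correlation structure.  Passing the recovery benchmark
therefore shows the geometry/segmentation machinery works under honest mixing
conditions, not that the pipeline is tuned for any particular real assay.

## Benchmark

Predicted territory maps are scored against ground truth with ARI and
variation of information (nats); `isolated` barcodes count as one extra
predicted cluster so no barcode is dropped from scoring.  The harness runs
10 replicates by default (the tests and acceptance script use 5 replicates
of 2,000 cells per regime, a desk-scale setting of the same conditions) and
reports medians and IQRs; a statistics utility applies Shapiro–Wilk,
Bartlett, Kruskal–Wallis and pairwise rank-sum tests across methods' score
tables.

The benchmark pipeline defaults use a 300-pixel canvas and a Gaussian
schedule of sigma 5 x 10 iterations.  At 2,000 barcodes a tile is ~6 px
across, so the effective blur (sigma ~16 px) averages over roughly two to
three tile widths — enough for mixed territories to converge to their mean
color while keeping band boundaries sharp at k-means scale.  The
segmentation function's own default schedule (sigma 2 x 3) is milder and
meant for denser real pucks at the 1,000-px canvas.

## Numerical choices and degenerate inputs

- Min-max of a constant vector returns zeros (valid color) rather than NaN.
- k-means ties in nearest-centroid resolve to the lowest cluster index; a k
  exceeding the number of distinct colors is reduced with a warning and
  labels are compacted.
- MTX input is 1-based per the Matrix Market standard and converted to
  0-based indices at the read boundary; barcode order always follows the
  coordinate file, gene order the counts file.
- Barcodes present in counts but absent from coordinates (and vice versa)
  are dropped with a logged warning; zero overlap is an error.  Barcodes
  with zero total counts are dropped at load — they are undefined under
  log-normalization.
- A single-barcode dataset tessellates to a full-canvas tile and isolates
  to the `isolated` group.
- VI values below 1e-12 are snapped to exactly 0 so identical partitions
  score 0.

## Limitations

- UMAP determinism is per-environment: identical seeds reproduce bitwise
  within one library stack, not across versions.
- The capture-radius graph is built per color cluster with a KD-tree; for
  degenerate radii near the assay diameter the pair list grows
  quadratically.
- Morphology and layering operate at pixel resolution; sub-pixel territory
  boundaries are not represented.
- The `cells_in_territories` mode requires externally supplied cell-type
  annotations (e.g. from a deconvolution tool); no deconvolution is
  performed here.
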