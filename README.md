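# tessella

Image-based detection of tissue territories in high-resolution spatial
transcriptomics (ST).

## The problem

Sequencing-based ST assays (Slide-seq, Seq-Scope, Visium, ...) measure a
gene-count vector at thousands of spatially indexed barcodes.  Spatial
domain detection asks: which barcodes belong to the same anatomical
territory?  Methods that assume neighboring barcodes are transcriptionally
similar fail in tissues where one territory interleaves several cell types
— at cellular resolution a bead sits on one cell, and its neighbor may be a
different type entirely.

`tessella` turns the assay into an image and the question into image
segmentation.  Each barcode's transcriptome becomes an RGB color (log-
normalization → 2,000 highly variable genes → 30 PCs → 3-D UMAP, each axis
min-max normalized to a color channel, B′ = (B − min B)/(max B − min B));
punctual coordinates are expanded into Voronoi-tile pixel sets; blurring
the painted image averages colors over space, so a mixed territory
converges to a characteristic color that iterative k-means segmentation
recovers.  Color clusters are then split into spatially contiguous
territories: barcodes of one cluster within a capture radius r = p · max
pairwise distance (default p = 0.05) of each other join the same territory,
and components under 50 barcodes form the `isolated` group.  Territories
support morphological editing (signed pixel steps, e.g. `[-5, 5]` =
erode 5 then dilate 5), concentric Sobel-peel layering, and marker
extraction (detection > 10% in a group, |logFC| ≥ 0.25, two-sided Wilcoxon
rank-sum, Bonferroni-corrected p < 0.05).

A built-in simulator generates ground-truthed pucks — 6,000 barcodes on the
unit square in four regimes (pure / uniform / exponential with
P_l = e^l / Σ e^l type proportions / dotted) — and a benchmark harness
scores recovery with the adjusted Rand index and variation of information.

## Worked example

```python
import tessella as ts

# a ground-truthed puck: 3 territories, each a different set of 3 cell types
cfg = ts.SimulationConfig(regime="uniform", n_cells=2000, seed=4)
puck = ts.simulate_puck(cfg)

# full pipeline: colors -> image -> iterative k-means -> territories
tm, ds = ts.run_pipeline(puck.dataset, ts.PipelineConfig(k_sequence=[3]), seed=4)
print("territories:", tm.territories,
      "isolated:", len(tm.barcodes(ts.ISOLATED)))

truth = puck.truth_labels(ds.barcode_ids)
pred = [tm.assignment[b] for b in ds.barcode_ids]
pred = [max(tm.territories) + 1 if p == ts.ISOLATED else p for p in pred]
print("ARI %.3f  VI %.3f" % (ts.adjusted_rand_index(truth, pred),
                             ts.variation_of_information(truth, pred)))

# markers of territory 1 against the rest
pairs = ts.build_groups(tm, "vs_all", 1)
de = ts.extract_markers(ds, pairs[0].group1, pairs[0].group2)
print(de.head(3)[["gene_id", "log_fc", "pct1", "pct2", "p_adjusted"]])
```

prints

```
territories: [1, 2, 3] isolated: 0
ARI 0.964  VI 0.130
     gene_id    log_fc      pct1      pct2    p_adjusted
0  gene_0094  0.910670  0.536189  0.331822  2.103995e-24
1  gene_0077  0.856572  0.528804  0.345427  5.189119e-22
2  gene_0089  0.821884  0.537666  0.352986  3.947843e-21
```

The three ground-truth territories are recovered almost exactly (ARI 0.96,
VI 0.13 nats), and the top markers are genes from the marker block of a
cell type present in territory 1 but rarer elsewhere — enriched about
2.5-fold (logFC ≈ 0.9, detected in ~54% of territory-1 barcodes vs ~33%
elsewhere) and significant after Bonferroni correction.

A shell interface mirrors the stages (`tessella simulate | embed | image |
segment | territories | morph | layers | markers | benchmark`); see
`tessella --help`.

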