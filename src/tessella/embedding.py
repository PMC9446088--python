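"""Count preprocessing and transcriptome-to-RGB color embedding.

The central idea of the method is to represent each barcode's transcriptome
as a single color so the assay can be treated as an image.  The route is:

1. log-normalize counts (library-size scaling to ``scale_factor``, then
   ``log1p``),
2. keep the top highly variable genes (HVGs),
3. per-gene z-scoring (clipped) and PCA,
4. either a 3-D UMAP of the PC scores (default) or the absolute scores on a
   slice of three PCs,
5. min-max normalize each latent axis into [0, 1] and read the three axes as
   the R, G, B channels.

Two barcodes with similar transcriptomes therefore receive similar colors,
which is what downstream image smoothing and segmentation exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import SpatialDataset

logger = logging.getLogger("tessella.embedding")

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 30
ZSCORE_CLIP = 10.0


@dataclass
class LatentEmbedding:
    """Latent coordinates (PC or UMAP space) for each barcode.

    ``scores`` is barcodes x d; ``loadings`` (genes x d) is populated for PCA
    only.  ``d`` must be at least 3 to feed the three color channels.
    """

    scores: np.ndarray
    barcode_ids: list[str]
    loadings: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("latent scores contain non-finite entries")
        if self.scores.shape[0] != len(self.barcode_ids):
            raise ValueError("scores rows != number of barcodes")


@dataclass
class ColorEmbedding:
    """Per-barcode RGB triple in [0, 1]^3.

    ``channel_assignment`` records which latent dimension feeds which channel.
    """

    rgb: np.ndarray
    barcode_ids: list[str]
    channel_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.shape != (len(self.barcode_ids), 3):
            raise ValueError("rgb must be (n_barcodes, 3)")
        if self.rgb.size and (self.rgb.min() < 0 or self.rgb.max() > 1):
            raise ValueError("rgb values outside [0, 1]")

    def lookup(self) -> dict[str, np.ndarray]:
        return {b: self.rgb[i] for i, b in enumerate(self.barcode_ids)}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def normalize_log(
    ds: SpatialDataset, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> sp.csr_matrix:
    """Library-size log-normalization: ``log(1 + count / total * scale_factor)``.

    Returns a sparse genes x barcodes float matrix of the same shape.  Zero
    counts stay exactly zero, so sparsity is preserved.  Barcodes with zero
    total counts must have been removed beforehand.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(ds.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ZeroDivisionError(
            "barcodes with zero total counts cannot be log-normalized"
        )
    # scale each column (barcode) by scale_factor / total, then log1p the data
    scale = scale_factor / totals
    mat = (ds.counts.astype(float) @ sp.diags(scale)).tocsr()
    mat.data = np.log1p(mat.data)
    return mat


def select_hvg(norm: sp.spmatrix | np.ndarray, n: int = DEFAULT_N_HVG) -> np.ndarray:
    """Indices of the ``n`` most variable genes of a normalized matrix.

    The variability statistic is the variance of standardized expression:
    each gene is centered and scaled by an expected standard deviation taken
    from a robust mean-variance trend (running median of the variance over
    ~20 mean-quantile bins, so a handful of genuinely hypervariable genes
    cannot inflate their own expectation), with standardized values clipped
    at sqrt(n_barcodes) so single outlier barcodes cannot dominate.  When
    too few genes are available to fit a trend (< 30 with positive variance)
    the statistic falls back to the dispersion variance/mean.  Deterministic
    for fixed input; constant genes rank last (statistic 0).
    """
    X = np.asarray(norm.todense() if sp.issparse(norm) else norm, dtype=float)
    n_genes, n_bc = X.shape
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs but only {n_genes} genes present")
    mu = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if n_bc > 1 else np.zeros(n_genes)
    stat = np.zeros(n_genes)
    pos = var > 0
    if pos.sum() >= 30:
        exp_var = _trend_expected_variance(mu[pos], var[pos])
        exp_sd = np.sqrt(exp_var)
        clip = np.sqrt(n_bc)
        Z = (X[pos] - mu[pos, None]) / exp_sd[:, None]
        np.clip(Z, -clip, clip, out=Z)
        stat[pos] = Z.var(axis=1, ddof=1)
    elif pos.any():
        stat[pos] = var[pos] / np.maximum(mu[pos], 1e-12)
    # stable ranking: statistic descending, gene order as tie-break
    order = np.lexsort((np.arange(n_genes), -stat))
    return np.sort(order[:n])


def _trend_expected_variance(mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Per-gene expected variance: median variance within mean-quantile bins."""
    n = len(mu)
    n_bins = max(1, min(20, n // 15))
    edges = np.quantile(mu, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, mu, side="right") - 1, 0, n_bins - 1)
    exp_var = np.empty(n)
    for b in range(n_bins):
        members = bins == b
        exp_var[members] = np.median(var[members]) if members.any() else np.nan
    return np.maximum(exp_var, 1e-12)


def compute_pca(
    norm: sp.spmatrix | np.ndarray,
    n_pcs: int = DEFAULT_N_PCS,
    barcode_ids: list[str] | None = None,
    clip: float = ZSCORE_CLIP,
) -> LatentEmbedding:
    """PCA of the z-scored (per gene, clipped at ``clip``) normalized matrix.

    ``norm`` is genes x barcodes (typically already restricted to HVGs).
    Returns scores (barcodes x n_pcs) and loadings (genes x n_pcs) ordered by
    explained variance.
    """
    X = np.asarray(norm.todense() if sp.issparse(norm) else norm, dtype=float)
    n_genes, n_bc = X.shape
    if n_pcs > min(n_genes, n_bc):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(genes, barcodes)={min(n_genes, n_bc)}"
        )
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True) if n_bc > 1 else np.ones((n_genes, 1))
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    pca = PCA(n_components=n_pcs, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(Z.T)
    if barcode_ids is None:
        barcode_ids = [str(i) for i in range(n_bc)]
    return LatentEmbedding(
        scores=scores,
        barcode_ids=list(barcode_ids),
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# latent space -> RGB
# ---------------------------------------------------------------------------


def minmax_channel(v: np.ndarray) -> np.ndarray:
    """Min-max normalize a vector into [0, 1]; a constant vector maps to zeros."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot min-max normalize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite entries")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def embed_umap_rgb(lat: LatentEmbedding, seed: int = 0, **umap_kwargs) -> ColorEmbedding:
    """3-D UMAP of the latent scores, min-max normalized into RGB.

    Deterministic for a fixed seed (single-threaded UMAP with a fixed random
    state).  Duplicate score rows are collapsed before embedding so barcodes
    with identical transcriptomes are guaranteed identical colors.
    """
    import umap

    scores = lat.scores
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 latent dimensions for RGB embedding")
    uniq, inverse = np.unique(scores, axis=0, return_inverse=True)
    n_uniq = uniq.shape[0]
    if n_uniq < 5:
        raise ValueError("too few distinct transcriptomes for a UMAP embedding")
    kwargs = dict(
        n_components=3,
        n_neighbors=min(15, n_uniq - 1),
        min_dist=0.1,
        random_state=seed,
    )
    kwargs.update(umap_kwargs)
    emb = umap.UMAP(**kwargs).fit_transform(uniq)
    if not np.isfinite(emb).all():
        raise ArithmeticError("UMAP produced non-finite coordinates")
    emb = emb[inverse]
    rgb = np.column_stack([minmax_channel(emb[:, c]) for c in range(3)])
    return ColorEmbedding(
        rgb=rgb,
        barcode_ids=list(lat.barcode_ids),
        channel_assignment={"R": "UMAP1", "G": "UMAP2", "B": "UMAP3"},
    )


def embed_pca_rgb(
    lat: LatentEmbedding, pcs: tuple[int, int, int] = (0, 1, 2)
) -> ColorEmbedding:
    """RGB from a slice of three principal components.

    Each channel takes the absolute score of the barcode on its PC — the sum
    of |loading| contributions to that component — then is min-max normalized
    into [0, 1].  Sign flips of a PC therefore leave the colors unchanged.
    """
    if len(set(pcs)) != 3:
        raise ValueError("PC slice must name three distinct components")
    if max(pcs) >= lat.scores.shape[1] or min(pcs) < 0:
        raise ValueError(f"PC indices {pcs} out of range for d={lat.scores.shape[1]}")
    rgb = np.column_stack(
        [minmax_channel(np.abs(lat.scores[:, p])) for p in pcs]
    )
    return ColorEmbedding(
        rgb=rgb,
        barcode_ids=list(lat.barcode_ids),
        channel_assignment={c: f"PC{p + 1}" for c, p in zip("RGB", pcs)},
    )


def embed_dataset(
    ds: SpatialDataset,
    method: str = "umap",
    n_hvg: int = DEFAULT_N_HVG,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    pcs: tuple[int, int, int] = (0, 1, 2),
) -> ColorEmbedding:
    """Convenience pipeline: normalize -> HVG -> PCA -> RGB colors."""
    norm = normalize_log(ds, scale_factor=scale_factor)
    hvg = select_hvg(norm, n=min(n_hvg, ds.n_genes))
    lat = compute_pca(
        norm[hvg], n_pcs=min(n_pcs, min(len(hvg), ds.n_barcodes)), barcode_ids=ds.barcode_ids
    )
    if method == "umap":
        return embed_umap_rgb(lat, seed=seed)
    if method == "pca":
        return embed_pca_rgb(lat, pcs=pcs)
    raise ValueError(f"unknown embedding method {method!r}")
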