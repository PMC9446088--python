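"""Image smoothing and iterative k-means color segmentation.

Territory detection works on the painted assay image: the color histogram is
optionally balanced, the image is smoothed (Gaussian / median / box blur,
optionally total-variation regularized), and colors are clustered with
k-means.  With a decreasing sequence of k values the color space shrinks
round by round — after each round every tile (or pixel) is repainted with
its cluster's mean color before the next round runs.  Clustering is applied
to center-pixel colors only by default (one observation per barcode); the
``all_pixels`` mode clusters every pixel and labels each barcode by its
center pixel's cluster.

k plays the role of a granularity resolution: it bounds the number of color
clusters, which territory isolation then splits spatially.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .imaging import ImageArray, TileMap

logger = logging.getLogger("tessella.segmentation")


@dataclass
class SmoothingConfig:
    """Per-round smoothing schedule.

    ``method`` is one of ``gaussian`` (``size`` = sigma in pixels),
    ``median`` or ``box`` (``size`` = odd window width); the filter is applied
    ``iterations`` times per channel.  ``tv_weight > 0`` adds
    total-variation denoising after the blurs.  ``equalize`` balances each
    channel's histogram once before the first round.
    """

    method: str = "gaussian"
    size: float = 2.0
    iterations: int = 3
    tv_weight: float = 0.0
    equalize: bool = True


@dataclass
class ColorClusterMap:
    """Per-barcode color-cluster labels (contiguous, 1-based)."""

    barcode_ids: list[str]
    cluster: np.ndarray
    k_history: list[int] = field(default_factory=list)
    final_image: ImageArray | None = None

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=int)
        if len(self.cluster) != len(self.barcode_ids):
            raise ValueError("one cluster label per barcode required")
        labels = np.unique(self.cluster)
        if len(labels) and not np.array_equal(labels, np.arange(1, len(labels) + 1)):
            raise ValueError("cluster indices must be contiguous starting at 1")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.barcode_ids, (int(c) for c in self.cluster)))


# ---------------------------------------------------------------------------
# pixel-level operators
# ---------------------------------------------------------------------------


def _equalize_channel(ch: np.ndarray) -> np.ndarray:
    vals, inverse, counts = np.unique(ch, return_inverse=True, return_counts=True)
    if len(vals) == 1:
        return ch.copy()
    cdf = np.cumsum(counts) / ch.size
    levels = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
    return levels[inverse].reshape(ch.shape)


def equalize_colors(img: ImageArray) -> ImageArray:
    """Per-channel histogram equalization, rescaled to span [0, 1].

    The mapping is the empirical CDF shifted so the lowest level maps to 0
    and the highest to 1; it is monotone, so the pixel ordering within a
    channel is preserved.  A constant channel is left unchanged.
    """
    out = np.stack(
        [_equalize_channel(img.array[:, :, c]) for c in range(3)], axis=-1
    )
    return ImageArray(array=out, tilemap=img.tilemap)


_FILTERS = {
    "gaussian": lambda ch, size: ndimage.gaussian_filter(ch, sigma=size, mode="nearest"),
    "median": lambda ch, size: ndimage.median_filter(ch, size=int(size), mode="nearest"),
    "box": lambda ch, size: ndimage.uniform_filter(ch, size=int(size), mode="nearest"),
}


def smooth(
    img: ImageArray, method: str = "gaussian", size: float = 2.0, iterations: int = 1
) -> ImageArray:
    """Apply the named blur ``iterations`` times per channel (0 = identity)."""
    if method not in _FILTERS:
        raise ValueError(f"unknown smoothing method {method!r}")
    if size <= 0:
        raise ValueError("kernel size must be positive")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    arr = img.array.copy()
    for _ in range(iterations):
        arr = np.stack(
            [_FILTERS[method](arr[:, :, c], size) for c in range(3)], axis=-1
        )
    return ImageArray(array=np.clip(arr, 0, 1), tilemap=img.tilemap)


def denoise_tv(img: ImageArray, weight: float = 0.1, max_iter: int = 200) -> ImageArray:
    """Nonlinear total-variation denoising (Chambolle projection algorithm).

    Larger weights remove more variation; the output's total variation never
    exceeds the input's.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    from skimage.restoration import denoise_tv_chambolle

    arr = denoise_tv_chambolle(
        img.array, weight=weight, channel_axis=-1, max_num_iter=max_iter
    )
    return ImageArray(array=np.clip(arr, 0, 1), tilemap=img.tilemap)


def total_variation(arr: np.ndarray) -> float:
    """Isotropic total variation summed over channels (test/diagnostic aid)."""
    tv = 0.0
    for c in range(arr.shape[2]):
        gr = np.diff(arr[:, :, c], axis=0)
        gc = np.diff(arr[:, :, c], axis=1)
        tv += float(np.abs(gr).sum() + np.abs(gc).sum())
    return tv


# ---------------------------------------------------------------------------
# iterative segmentation
# ---------------------------------------------------------------------------


def _apply_smoothing(img: ImageArray, cfg: SmoothingConfig) -> ImageArray:
    out = smooth(img, method=cfg.method, size=cfg.size, iterations=cfg.iterations)
    if cfg.tv_weight > 0:
        out = denoise_tv(out, weight=cfg.tv_weight)
    return out


def segment_iterative(
    img: ImageArray,
    k_sequence: list[int],
    mode: str = "center_pixel",
    smoothing: SmoothingConfig | None = None,
    seed: int = 0,
) -> ColorClusterMap:
    """Iterative smooth + k-means segmentation of the assay image.

    For each k in ``k_sequence``: smooth, cluster colors into k groups
    (center-pixel colors only, or all pixels in ``all_pixels`` mode), then
    repaint with the cluster mean colors before the next round.  Each barcode
    ends with the cluster of its center pixel.  Deterministic for a fixed
    seed (k-means++ with 10 restarts).  If a round requests more clusters
    than distinct colors remain, k is reduced with a warning and the final
    indices are compacted.
    """
    if not k_sequence:
        raise ValueError("k_sequence must be nonempty")
    tm = img.tilemap
    n = len(tm.barcode_ids)
    for k in k_sequence:
        if not (2 <= k <= n):
            raise ValueError(f"each k must be in [2, n_barcodes]; got {k}")
    if mode not in ("center_pixel", "all_pixels"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = smoothing if smoothing is not None else SmoothingConfig()

    current = ImageArray(array=img.array.copy(), tilemap=tm)
    if cfg.equalize:
        current = equalize_colors(current)

    cr, cc = tm.centers[:, 0], tm.centers[:, 1]
    labels = np.zeros(n, dtype=int)
    applied: list[int] = []
    for k in k_sequence:
        current = _apply_smoothing(current, cfg)
        arr = current.array
        if mode == "center_pixel":
            obs = arr[cr, cc]
        else:
            obs = arr.reshape(-1, 3)
        n_distinct = len(np.unique(obs, axis=0))
        k_eff = min(k, n_distinct)
        if k_eff < k:
            warnings.warn(
                f"only {n_distinct} distinct colors; reducing k from {k} to {k_eff}",
                RuntimeWarning,
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k-means convergence chatter
            km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed).fit(obs)
        if mode == "center_pixel":
            labels = km.labels_
            tile_color = km.cluster_centers_[labels]
            arr = tile_color[tm.owner]
        else:
            pixel_labels = km.labels_.reshape(arr.shape[:2])
            labels = pixel_labels[cr, cc]
            arr = km.cluster_centers_[km.labels_].reshape(arr.shape)
        current = ImageArray(array=np.clip(arr, 0, 1), tilemap=tm)
        applied.append(k_eff)

    # compact to contiguous 1-based labels
    uniq = np.unique(labels)
    remap = {int(u): i + 1 for i, u in enumerate(uniq)}
    final = np.array([remap[int(v)] for v in labels], dtype=int)
    return ColorClusterMap(
        barcode_ids=list(tm.barcode_ids),
        cluster=final,
        k_history=applied,
        final_image=current,
    )
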