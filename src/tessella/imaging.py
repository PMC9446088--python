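"""From punctual barcode coordinates to a contiguous RGB image.

Barcode positions in a sequencing-based ST assay are scattered points, not a
pixel grid.  To apply image processing, each barcode is expanded into a
*tile* — the set of pixels closer to it than to any other barcode (a discrete
Voronoi tessellation at pixel resolution) — and every pixel of a tile is
painted with its barcode's color.  Before tessellating, stray barcodes
falling into low-density grid sections are removed.

Conventions: pixel coordinates are 0-based (row, col) with row 0 at the top;
assay y increases upward and is flipped exactly once here.  Ties in
nearest-barcode distance break to the lowest barcode index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import ConsistencyError, SpatialDataset
from .embedding import ColorEmbedding

logger = logging.getLogger("tessella.imaging")

DEFAULT_LONG_SIDE = 1000
DEFAULT_STRAY_GRID = 50
DEFAULT_STRAY_QUANTILE = 0.01


@dataclass
class TileMap:
    """Pixel ownership after Voronoi tessellation and rasterization.

    ``owner`` is an (H, W) integer array mapping every in-bounds pixel to the
    index of its barcode in ``barcode_ids`` (a partition: each pixel has
    exactly one owner).  ``centers`` holds each barcode's center pixel — the
    pixel of its original coordinate — as (row, col).
    """

    owner: np.ndarray
    centers: np.ndarray
    barcode_ids: list[str]

    def __post_init__(self) -> None:
        self.owner = np.asarray(self.owner, dtype=np.int32)
        self.centers = np.asarray(self.centers, dtype=int)
        n = len(self.barcode_ids)
        if self.centers.shape != (n, 2):
            raise ValueError("centers must be (n_barcodes, 2)")

    @property
    def image_height(self) -> int:
        return self.owner.shape[0]

    @property
    def image_width(self) -> int:
        return self.owner.shape[1]

    def mask_for(self, indices: np.ndarray) -> np.ndarray:
        """Boolean (H, W) mask of the pixels owned by the given barcodes."""
        return np.isin(self.owner, np.asarray(indices, dtype=self.owner.dtype))

    def tile_sizes(self) -> np.ndarray:
        return np.bincount(self.owner.ravel(), minlength=len(self.barcode_ids))


@dataclass
class ImageArray:
    """An H x W x 3 image in [0, 1] plus the tile map it was painted from."""

    array: np.ndarray
    tilemap: TileMap

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3 or self.array.shape[2] != 3:
            raise ValueError("image array must be H x W x 3")
        if self.array.size and (self.array.min() < -1e-9 or self.array.max() > 1 + 1e-9):
            raise ValueError("image values outside [0, 1]")
        self.array = np.clip(self.array, 0.0, 1.0)


# ---------------------------------------------------------------------------
# stray filtering
# ---------------------------------------------------------------------------


def filter_stray(
    ds: SpatialDataset,
    grid_cells: int = DEFAULT_STRAY_GRID,
    density_quantile: float = DEFAULT_STRAY_QUANTILE,
) -> SpatialDataset:
    """Drop barcodes in low-density sections of a grid over the bounding box.

    A ``grid_cells`` x ``grid_cells`` grid is overlaid on the coordinate
    bounding box; barcodes in sections whose occupancy is strictly below the
    ``density_quantile`` quantile of the *nonzero* section occupancies are
    removed.  ``density_quantile=0`` is the identity.
    """
    if grid_cells < 1:
        raise ValueError("grid_cells must be >= 1")
    if not (0 <= density_quantile < 1):
        raise ValueError("density_quantile must be in [0, 1)")
    x, y = ds.coords[:, 0], ds.coords[:, 1]
    gx = _grid_index(x, grid_cells)
    gy = _grid_index(y, grid_cells)
    section = gx * grid_cells + gy
    counts = np.bincount(section, minlength=grid_cells * grid_cells)
    nonzero = counts[counts > 0]
    threshold = np.quantile(nonzero, density_quantile)
    keep = counts[section] >= threshold
    if not keep.any():
        raise ValueError("stray filtering removed every barcode")
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("stray filter dropped %d / %d barcodes", dropped, ds.n_barcodes)
    if dropped == 0:
        return ds
    return ds.subset_barcodes(np.flatnonzero(keep))


def _grid_index(v: np.ndarray, cells: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(len(v), dtype=int)
    idx = np.floor((v - lo) / (hi - lo) * cells).astype(int)
    return np.clip(idx, 0, cells - 1)


# ---------------------------------------------------------------------------
# tessellation and rasterization
# ---------------------------------------------------------------------------


def tessellate(
    ds: SpatialDataset,
    height: int | None = None,
    width: int | None = None,
    long_side: int = DEFAULT_LONG_SIDE,
) -> TileMap:
    """Discrete Voronoi tessellation of the pixel canvas by barcode sites.

    Coordinates are mapped affinely onto the canvas preserving aspect ratio
    (y flipped so larger assay y is higher in the image).  Every in-bounds
    pixel is assigned to its nearest barcode in scaled coordinates; exact
    ties break to the lowest barcode index.  Each barcode's rounded position
    becomes its center pixel; collisions are shifted to the nearest free
    pixel so every barcode owns at least its center.
    """
    if ds.n_barcodes < 1:
        raise ValueError("need at least one barcode")
    x, y = ds.coords[:, 0], ds.coords[:, 1]
    xr = float(x.max() - x.min())
    yr = float(y.max() - y.min())
    if height is None or width is None:
        long_range = max(xr, yr)
        if long_range == 0:
            height = height or 1
            width = width or 1
            scale = 1.0
        else:
            scale = (long_side - 1) / long_range
            width = max(1, int(round(xr * scale)) + 1)
            height = max(1, int(round(yr * scale)) + 1)
    else:
        sx = (width - 1) / xr if xr > 0 else np.inf
        sy = (height - 1) / yr if yr > 0 else np.inf
        scale = min(sx, sy)
        if not np.isfinite(scale):
            scale = 1.0
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1 pixel")

    cols = (x - x.min()) * scale
    rows = (y.max() - y) * scale
    # center the used extent on the canvas
    cols += (width - 1 - (cols.max() if len(cols) else 0)) / 2
    rows += (height - 1 - (rows.max() if len(rows) else 0)) / 2

    owner = _discrete_voronoi(rows, cols, height, width)
    centers = _place_centers(rows, cols, height, width)
    # guarantee each barcode owns its center pixel (only matters when two
    # barcodes round onto the same pixel)
    owner[centers[:, 0], centers[:, 1]] = np.arange(len(centers), dtype=owner.dtype)
    return TileMap(owner=owner, centers=centers, barcode_ids=list(ds.barcode_ids))


def _discrete_voronoi(rows: np.ndarray, cols: np.ndarray, h: int, w: int) -> np.ndarray:
    n = len(rows)
    sites = np.column_stack([rows, cols])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(sites)
    k = min(8, n)
    dist, idx = tree.query(pixels, k=k)
    if k == 1:
        return idx.reshape(h, w).astype(np.int32)
    # lowest barcode index among exactly-tied nearest sites
    tied = dist == dist[:, :1]
    cand = np.where(tied, idx, n)
    return cand.min(axis=1).reshape(h, w).astype(np.int32)


def _place_centers(rows: np.ndarray, cols: np.ndarray, h: int, w: int) -> np.ndarray:
    """Round positions to pixels; resolve collisions to nearest free pixels."""
    r = np.clip(np.rint(rows).astype(int), 0, h - 1)
    c = np.clip(np.rint(cols).astype(int), 0, w - 1)
    centers = np.column_stack([r, c])
    taken: set[tuple[int, int]] = set()
    for i in range(len(centers)):
        p = (int(centers[i, 0]), int(centers[i, 1]))
        if p in taken:
            p = _nearest_free(p, taken, h, w)
            centers[i] = p
        taken.add(p)
    return centers


def _nearest_free(p: tuple[int, int], taken: set, h: int, w: int) -> tuple[int, int]:
    r0, c0 = p
    for radius in range(1, max(h, w) + 1):
        ring = []
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if max(abs(dr), abs(dc)) != radius:
                    continue
                r, c = r0 + dr, c0 + dc
                if 0 <= r < h and 0 <= c < w and (r, c) not in taken:
                    ring.append((dr * dr + dc * dc, r, c))
        if ring:
            ring.sort()
            return (ring[0][1], ring[0][2])
    raise ValueError("no free pixel available for a barcode center")


def build_image(tm: TileMap, colors: ColorEmbedding) -> ImageArray:
    """Paint every pixel of each tile with its barcode's RGB color."""
    lookup = {b: i for i, b in enumerate(colors.barcode_ids)}
    missing = [b for b in tm.barcode_ids if b not in lookup]
    if missing:
        raise ConsistencyError(f"no color for barcodes: {missing[:5]}")
    rgb = colors.rgb[[lookup[b] for b in tm.barcode_ids]]
    return ImageArray(array=rgb[tm.owner], tilemap=tm)


def resize_image(img: ImageArray, scale: float) -> ImageArray:
    """Nearest-neighbor resize of the image and its tile map.

    All barcodes are retained: center pixels are remapped into the new
    canvas and colliding centers are shifted to the nearest free pixel, then
    ownership of each center is restored to its barcode.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    h, w = img.array.shape[:2]
    h2, w2 = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    src_r = np.minimum((np.arange(h2) + 0.5) * h / h2, h - 1).astype(int)
    src_c = np.minimum((np.arange(w2) + 0.5) * w / w2, w - 1).astype(int)
    arr = img.array[src_r][:, src_c]
    owner = img.tilemap.owner[src_r][:, src_c]

    old = img.tilemap.centers.astype(float)
    rows = np.clip(np.floor((old[:, 0] + 0.5) * h2 / h), 0, h2 - 1)
    cols = np.clip(np.floor((old[:, 1] + 0.5) * w2 / w), 0, w2 - 1)
    centers = _place_centers(rows, cols, h2, w2)
    owner = owner.copy()
    owner[centers[:, 0], centers[:, 1]] = np.arange(len(centers), dtype=owner.dtype)
    tm = TileMap(owner=owner, centers=centers, barcode_ids=list(img.tilemap.barcode_ids))
    return ImageArray(array=arr, tilemap=tm)
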