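"""Territory isolation, morphological manipulation and concentric layering.

A color cluster groups barcodes by transcriptional signature but not by
location: the same signature can occur in disconnected parts of the tissue.
Territories are the spatially contiguous pieces of each color cluster —
connected components of the graph linking same-cluster barcodes within a
*capture radius* (a user-chosen proportion of the maximum pairwise barcode
distance in assay space).  Components with too few barcodes fall into the
``isolated`` group.

Territories live a second life as pixel masks (via the tile map), where they
can be grown, shrunk, cleaned or filled with dilation/erosion sequences, and
peeled into concentric layers by repeatedly removing their Sobel-detected
edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree

from .io import ISOLATED, SpatialDataset, TerritoryMap
from .imaging import TileMap
from .segmentation import ColorClusterMap

logger = logging.getLogger("tessella.territories")

DEFAULT_CAPTURE_PROP = 0.05
DEFAULT_MIN_BARCODES = 50


@dataclass
class MorphologyFactor:
    """Ordered dilation/erosion steps in pixels.

    Positive steps dilate, negative steps erode; e.g. ``[-5, 5]`` is an
    opening (erode then dilate) that cleans specks, ``[5, -5]`` a closing
    that fills holes.
    """

    steps: list[int]

    def __post_init__(self) -> None:
        self.steps = [int(s) for s in self.steps]
        if not self.steps:
            raise ValueError("morphology factor needs at least one step")
        if any(s == 0 for s in self.steps):
            raise ValueError("morphology steps must be nonzero integers")


@dataclass
class LayerMap:
    """Per-barcode concentric layer index within one territory (1 = edge)."""

    layer_of: dict[str, int]
    territory: int | str

    def __post_init__(self) -> None:
        labels = sorted(set(self.layer_of.values()))
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"layer indices must be contiguous from 1: {labels}")

    @property
    def n_layers(self) -> int:
        return len(set(self.layer_of.values()))

    def barcodes(self, layer: int) -> list[str]:
        return [b for b, v in self.layer_of.items() if v == layer]


@dataclass
class MorphResult:
    """Outcome of a morphology sequence: final mask + captured barcodes."""

    mask: np.ndarray
    barcode_ids: list[str]


# ---------------------------------------------------------------------------
# territory isolation
# ---------------------------------------------------------------------------


def max_pairwise_distance(coords: np.ndarray) -> float:
    """Diameter of the barcode point set (via convex hull for large n)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return 0.0
    pts = coords
    if n > 500:
        try:
            pts = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (collinear) input
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def isolate_territories(
    ccm: ColorClusterMap,
    ds: SpatialDataset,
    capture_prop: float = DEFAULT_CAPTURE_PROP,
    min_barcodes: int = DEFAULT_MIN_BARCODES,
    isolate_distant: bool = False,
) -> TerritoryMap:
    """Split color clusters into spatially contiguous territories.

    The capture radius is ``capture_prop`` times the maximum pairwise
    distance between all barcodes (assay coordinates).  Within each color
    cluster, territories are the connected components of the graph linking
    barcodes at distance <= radius.  Components with fewer than
    ``min_barcodes`` barcodes are labeled :data:`ISOLATED`; with
    ``isolate_distant`` a component whose nearest other component lies
    beyond the capture radius is also isolated.  Surviving territories are
    renumbered 1..T by decreasing size (ties by smallest barcode index).
    """
    if not (0 < capture_prop < 1):
        raise ValueError("capture_prop must be in (0, 1)")
    idx = ds.index_of(ccm.barcode_ids)
    coords = ds.coords[idx]
    n = len(coords)
    if n == 1:
        return TerritoryMap({ccm.barcode_ids[0]: ISOLATED})
    radius = capture_prop * max_pairwise_distance(coords)

    comp_members: list[np.ndarray] = []  # positions into ccm.barcode_ids
    for cluster in np.unique(ccm.cluster):
        members = np.flatnonzero(ccm.cluster == cluster)
        comp_members.extend(_threshold_components(coords[members], radius, members))

    flagged = [len(m) < min_barcodes for m in comp_members]
    if isolate_distant and len(comp_members) > 1:
        trees = [cKDTree(coords[m]) for m in comp_members]
        for i, m in enumerate(comp_members):
            near = min(
                trees[j].query(coords[m], k=1)[0].min()
                for j in range(len(comp_members))
                if j != i
            )
            if near > radius:
                flagged[i] = True

    kept = [
        (len(m), int(m.min()), m) for m, f in zip(comp_members, flagged) if not f
    ]
    kept.sort(key=lambda t: (-t[0], t[1]))
    assignment: dict[str, int | str] = {}
    for label, (_, _, m) in enumerate(kept, start=1):
        for pos in m:
            assignment[ccm.barcode_ids[pos]] = label
    for m, f in zip(comp_members, flagged):
        if f:
            for pos in m:
                assignment[ccm.barcode_ids[pos]] = ISOLATED
    return TerritoryMap(assignment)


def _threshold_components(
    points: np.ndarray, radius: float, members: np.ndarray
) -> list[np.ndarray]:
    """Connected components of the <=radius graph; returns member-index arrays."""
    m = len(points)
    if m == 1:
        return [members.copy()]
    pairs = cKDTree(points).query_pairs(radius, output_type="ndarray")
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    )
    n_comp, labels = connected_components(graph, directed=False)
    return [members[labels == c] for c in range(n_comp)]


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _square(halfwidth: int) -> np.ndarray:
    return np.ones((2 * halfwidth + 1, 2 * halfwidth + 1), dtype=bool)


def territory_mask(tm: TerritoryMap, territory: int | str, tilemap: TileMap) -> np.ndarray:
    """Boolean pixel mask of a territory's tiles."""
    barcodes = tm.barcodes(territory)
    if not barcodes:
        raise KeyError(f"territory {territory!r} has no barcodes")
    lookup = {b: i for i, b in enumerate(tilemap.barcode_ids)}
    idx = np.array([lookup[b] for b in barcodes], dtype=int)
    return tilemap.mask_for(idx)


def morph_territory(
    tm: TerritoryMap,
    territory: int | str,
    tilemap: TileMap,
    mf: MorphologyFactor,
) -> MorphResult:
    """Apply a dilation/erosion sequence to a territory's pixel mask.

    Each step uses a square structuring element of half-width |step|.  The
    new territory consists of the barcodes whose center pixel lies inside
    the final mask — dilation may capture barcodes of neighboring
    territories, erosion may drop barcodes.  An erosion that empties the
    mask returns an empty result with a warning.
    """
    mask = territory_mask(tm, territory, tilemap)
    for step in mf.steps:
        op = ndimage.binary_dilation if step > 0 else ndimage.binary_erosion
        mask = op(mask, structure=_square(abs(step)))
        if not mask.any():
            warnings.warn(
                f"territory {territory!r} vanished during morphology",
                RuntimeWarning,
                stacklevel=2,
            )
            return MorphResult(mask=mask, barcode_ids=[])
    inside = mask[tilemap.centers[:, 0], tilemap.centers[:, 1]]
    return MorphResult(
        mask=mask,
        barcode_ids=[b for b, keep in zip(tilemap.barcode_ids, inside) if keep],
    )


# ---------------------------------------------------------------------------
# layering
# ---------------------------------------------------------------------------


def _sobel_boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with nonzero X-Y Sobel gradient magnitude."""
    f = mask.astype(float)
    gr = ndimage.sobel(f, axis=0, mode="nearest")
    gc = ndimage.sobel(f, axis=1, mode="nearest")
    return (np.hypot(gr, gc) > 1e-9) & mask


def layer_territory(
    tm: TerritoryMap,
    territory: int | str,
    tilemap: TileMap,
    n_layers_out: int | None = None,
) -> LayerMap:
    """Peel a territory into concentric layers from the edge inwards.

    Iteratively: binarize the remaining territory mask, Sobel-detect its
    edge, pool every barcode owning at least one edge pixel into the next
    layer and remove it; repeat until no barcode remains.  If the edge
    detector marks nothing (e.g. the mask fills the canvas) all remaining
    barcodes form the final layer, guaranteeing termination.  With
    ``n_layers_out`` the raw layers are merged, outermost first, into groups
    of near-equal raw-layer count.
    """
    barcodes = tm.barcodes(territory)
    if not barcodes:
        raise KeyError(f"territory {territory!r} has no barcodes")
    lookup = {b: i for i, b in enumerate(tilemap.barcode_ids)}
    remaining = {lookup[b] for b in barcodes}
    id_of = {i: b for b, i in lookup.items()}

    raw_layers: list[list[int]] = []
    while remaining:
        idx = np.fromiter(remaining, dtype=int)
        mask = tilemap.mask_for(idx)
        boundary = _sobel_boundary(mask)
        owners = np.unique(tilemap.owner[boundary])
        layer = sorted(set(owners.tolist()) & remaining)
        if not layer:  # degenerate: no detectable edge
            layer = sorted(remaining)
        raw_layers.append(layer)
        remaining.difference_update(layer)

    if n_layers_out is not None:
        if n_layers_out > len(raw_layers):
            raise ValueError(
                f"cannot merge {len(raw_layers)} raw layers into {n_layers_out}"
            )
        groups = np.array_split(np.arange(len(raw_layers)), n_layers_out)
        merged = [sorted(sum((raw_layers[i] for i in g), [])) for g in groups]
        raw_layers = merged

    layer_of = {
        id_of[i]: li + 1 for li, layer in enumerate(raw_layers) for i in layer
    }
    return LayerMap(layer_of=layer_of, territory=territory)
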