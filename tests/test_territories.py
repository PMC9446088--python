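import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import tessella as ts
from tessella.io import ISOLATED
from tessella.segmentation import ColorClusterMap
from tessella.territories import (
    LayerMap,
    MorphologyFactor,
    isolate_territories,
    layer_territory,
    max_pairwise_distance,
    morph_territory,
)

from conftest import make_dataset, make_grid_tilemap


def _ccm(ids, clusters):
    return ColorClusterMap(barcode_ids=list(ids), cluster=np.asarray(clusters))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_components(coords, clusters, radius):
    """Single-linkage components of the <=radius graph, per cluster, by BFS."""
    n = len(coords)
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in range(n):
                if not seen[k] and clusters[k] == clusters[j] and d[j, k] <= radius:
                    seen[k] = True
                    stack.append(k)
        comps.append(sorted(comp))
    return comps


def shift_dilate(mask, s):
    """Reference dilation with a (2s+1)^2 square element, by explicit shifts."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for dr in range(-s, s + 1):
        for dc in range(-s, s + 1):
            src = mask[
                max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
            ]
            out[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)] |= src
    return out


def shift_erode(mask, s):
    """Reference erosion; pixels outside the canvas count as background."""
    h, w = mask.shape
    out = np.ones_like(mask)
    for dr in range(-s, s + 1):
        for dc in range(-s, s + 1):
            shifted = np.zeros_like(mask)
            src = mask[
                max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
            ]
            shifted[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)] = src
            out &= shifted
    return out


# ---------------------------------------------------------------------------
# territory isolation
# ---------------------------------------------------------------------------


def test_isolation_hand_case():
    coords = np.array([(0.0, 0.0), (0.0, 1.0), (10.0, 10.0)])
    ds = make_dataset(np.ones((1, 3), dtype=int), coords)
    # max distance = sqrt(200) ~ 14.14; capture 0.15 -> radius ~ 2.12
    tm = isolate_territories(
        _ccm(ds.barcode_ids, [1, 1, 1]), ds, capture_prop=0.15, min_barcodes=1
    )
    assert tm.assignment["b0"] == tm.assignment["b1"] == 1
    assert tm.assignment["b2"] == 2  # smaller component ranks second


def test_capture_prop_near_one_recovers_color_clusters():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 1, size=(40, 2))
    ds = make_dataset(np.ones((1, 40), dtype=int), coords)
    clusters = rng.integers(1, 4, size=40)
    clusters[:3] = [1, 2, 3]  # make labels contiguous
    tm = isolate_territories(_ccm(ds.barcode_ids, clusters), ds,
                             capture_prop=0.99, min_barcodes=1)
    pred = np.array([tm.assignment[b] for b in ds.barcode_ids])
    assert ts.adjusted_rand_index(clusters, pred) == 1.0


def test_small_component_becomes_isolated():
    coords = np.array([(0.0, 0.0), (0.0, 1.0), (1.0, 0.0)])
    ds = make_dataset(np.ones((1, 3), dtype=int), coords)
    tm = isolate_territories(
        _ccm(ds.barcode_ids, [1, 1, 1]), ds, capture_prop=0.9, min_barcodes=50
    )
    assert all(v == ISOLATED for v in tm.assignment.values())


def test_isolation_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(1)
    for trial in range(10):
        n = int(rng.integers(5, 120))
        coords = rng.uniform(0, 1, size=(n, 2))
        k = int(rng.integers(1, 5))
        clusters = rng.integers(0, k, size=n)
        clusters[:k] = np.arange(k)
        capture = float(rng.uniform(0.02, 0.4))
        ds = make_dataset(np.ones((1, n), dtype=int), coords)
        ccm = _ccm(ds.barcode_ids, clusters - clusters.min() + 1)
        tm = isolate_territories(ccm, ds, capture_prop=capture, min_barcodes=1)
        radius = capture * max_pairwise_distance(coords)
        comps = brute_force_components(coords, clusters, radius)
        oracle = np.empty(n, dtype=int)
        for label, comp in enumerate(comps):
            oracle[comp] = label
        pred = np.array([tm.assignment[b] for b in ds.barcode_ids])
        assert ts.adjusted_rand_index(oracle, pred) == 1.0


def test_territories_partition_non_isolated_barcodes():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 1, size=(80, 2))
    ds = make_dataset(np.ones((1, 80), dtype=int), coords)
    tm = isolate_territories(_ccm(ds.barcode_ids, np.ones(80, int)), ds,
                             capture_prop=0.05, min_barcodes=3)
    assert set(tm.assignment) == set(ds.barcode_ids)  # every barcode labeled
    labels = tm.territories
    assert labels == list(range(1, len(labels) + 1))  # contiguous


def test_single_barcode_is_isolated():
    ds = make_dataset(np.ones((1, 1), dtype=int), [(0.0, 0.0)])
    tm = isolate_territories(_ccm(ds.barcode_ids, [1]), ds, capture_prop=0.5)
    assert tm.assignment["b0"] == ISOLATED


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _square_territory(canvas, r0, c0, side):
    """Grid tile map + territory map holding a solid square of 1-px tiles."""
    tilemap = make_grid_tilemap(canvas, canvas)
    owner = tilemap.owner
    ids = [
        tilemap.barcode_ids[owner[r, c]]
        for r in range(r0, r0 + side)
        for c in range(c0, c0 + side)
    ]
    assignment = {b: 1 for b in ids}
    return tilemap, ts.TerritoryMap(assignment)


def test_opening_of_large_square_is_identity():
    tilemap, tm = _square_territory(30, 5, 5, 20)
    before = np.zeros((30, 30), bool)
    before[5:25, 5:25] = True
    res = morph_territory(tm, 1, tilemap, MorphologyFactor([-5, 5]))
    assert np.array_equal(res.mask, before)
    assert sorted(res.barcode_ids) == sorted(tm.barcodes(1))


def test_single_pixel_territory_removed_by_opening():
    tilemap, tm = _square_territory(9, 4, 4, 1)
    with pytest.warns(RuntimeWarning):
        res = morph_territory(tm, 1, tilemap, MorphologyFactor([-1, 1]))
    assert not res.mask.any() and res.barcode_ids == []


def test_dilation_grows_square_by_step():
    tilemap, tm = _square_territory(20, 5, 5, 10)
    res = morph_territory(tm, 1, tilemap, MorphologyFactor([2]))
    expected = np.zeros((20, 20), bool)
    expected[3:17, 3:17] = True  # 10x10 -> 14x14
    assert np.array_equal(res.mask, expected)


def test_morphology_matches_shift_oracle_on_random_masks():
    rng = np.random.default_rng(3)
    tilemap = make_grid_tilemap(15, 15)
    for trial in range(10):
        mask = rng.random((15, 15)) < 0.4
        if not mask.any():
            continue
        ids = [tilemap.barcode_ids[i] for i in np.flatnonzero(mask.ravel())]
        tm = ts.TerritoryMap({b: 1 for b in ids})
        s = int(rng.integers(1, 3))
        dil = morph_territory(tm, 1, tilemap, MorphologyFactor([s])).mask
        assert np.array_equal(dil, shift_dilate(mask, s))
        assert not (mask & ~dil).any()  # monotone: mask subset of dilation
        ero_oracle = shift_erode(mask, s)
        if ero_oracle.any():
            ero = morph_territory(tm, 1, tilemap, MorphologyFactor([-s])).mask
            assert np.array_equal(ero, ero_oracle)
            opening = morph_territory(tm, 1, tilemap, MorphologyFactor([-s, s])).mask
            closing = morph_territory(tm, 1, tilemap, MorphologyFactor([s, -s])).mask
            assert not (opening & ~mask).any()  # opening subset of original
            assert not (mask & ~closing).any()  # original subset of closing


def test_morphology_factor_validation():
    with pytest.raises(ValueError):
        MorphologyFactor([])
    with pytest.raises(ValueError):
        MorphologyFactor([2, 0])


# ---------------------------------------------------------------------------
# layering
# ---------------------------------------------------------------------------


def test_square_peels_into_concentric_rings():
    tilemap, tm = _square_territory(9, 2, 2, 5)
    lm = layer_territory(tm, 1, tilemap)
    sizes = [len(lm.barcodes(i)) for i in range(1, lm.n_layers + 1)]
    assert sizes == [16, 8, 1]


def test_single_barcode_territory_single_layer():
    tilemap, tm = _square_territory(5, 2, 2, 1)
    lm = layer_territory(tm, 1, tilemap)
    assert lm.n_layers == 1 and len(lm.layer_of) == 1


def test_layer_merging_groups_adjacent_layers():
    # an 11x11 square peels into 6 rings: 40, 32, 24, 16, 8, 1
    tilemap, tm = _square_territory(15, 2, 2, 11)
    raw = layer_territory(tm, 1, tilemap)
    assert [len(raw.barcodes(i)) for i in range(1, 7)] == [40, 32, 24, 16, 8, 1]
    merged = layer_territory(tm, 1, tilemap, n_layers_out=3)
    assert [len(merged.barcodes(i)) for i in range(1, 4)] == [72, 40, 9]


def test_layer_merge_rejects_too_many_groups():
    tilemap, tm = _square_territory(9, 2, 2, 5)  # 3 raw layers
    with pytest.raises(ValueError):
        layer_territory(tm, 1, tilemap, n_layers_out=4)


def test_layers_partition_territory_on_random_shapes():
    rng = np.random.default_rng(4)
    tilemap = make_grid_tilemap(12, 12)
    for trial in range(5):
        mask = rng.random((12, 12)) < 0.5
        if not mask.any():
            continue
        ids = [tilemap.barcode_ids[i] for i in np.flatnonzero(mask.ravel())]
        tm = ts.TerritoryMap({b: 1 for b in ids})
        lm = layer_territory(tm, 1, tilemap)
        assert sorted(lm.layer_of) == sorted(ids)  # exactly one layer each
        assert lm.n_layers <= len(ids)  # termination bound
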