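"""Territory-aware differential gene expression.

Marker extraction between two barcode groups follows the standard
single-cell convention: genes must be detected in more than ``min_pct`` of
barcodes in at least one group and show an absolute natural-log fold change
of at least ``min_abs_logfc`` (the threshold applies to up- and
down-regulation alike); surviving genes are tested with a two-sided Wilcoxon
rank-sum test and Bonferroni-corrected over the genes actually tested.

Group pairs can be built in five modes: a territory against all others
combined, a territory against each other territory, one territory set
against another, cells of one type shared between two territory sets (needs
external cell-type annotations, with a >30-cells-per-side floor), and layer
against layer within a territory.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .io import ISOLATED, SpatialDataset, TerritoryMap
from .imaging import ImageArray, TileMap
from .embedding import minmax_channel, normalize_log
from .territories import LayerMap

logger = logging.getLogger("tessella.diffexp")

DEFAULT_MIN_PCT = 0.10
DEFAULT_MIN_ABS_LOGFC = 0.25
DEFAULT_ALPHA = 0.05
MIN_CELLS_PER_SIDE = 30

DE_COLUMNS = ["gene_id", "log_fc", "pct1", "pct2", "p_value", "p_adjusted", "significant"]


class GroupPair(NamedTuple):
    name: str
    group1: list[str]
    group2: list[str]


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with
    mid-ranks, tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _log_mean_expression(norm_block: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(values)) + 1) per gene — fold changes on expression scale."""
    return np.log(np.expm1(norm_block).mean(axis=1) + 1.0)


def extract_markers(
    ds: SpatialDataset,
    group1: Iterable[str],
    group2: Iterable[str],
    min_pct: float = DEFAULT_MIN_PCT,
    min_abs_logfc: float = DEFAULT_MIN_ABS_LOGFC,
    alpha: float = DEFAULT_ALPHA,
    norm: sp.spmatrix | None = None,
) -> pd.DataFrame:
    """Differential expression between two disjoint barcode groups.

    Returns a DataFrame with one row per gene passing both filters
    (detection fraction strictly above ``min_pct`` in at least one group and
    |log fold change| >= ``min_abs_logfc``), sorted by adjusted p-value then
    |log_fc|.  ``log_fc`` is the natural-log fold change of mean normalized
    expression, group1 minus group2.  ``significant`` flags Bonferroni
    p < ``alpha``.
    """
    g1 = list(group1)
    g2 = list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be nonempty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    i1 = ds.index_of(g1)
    i2 = ds.index_of(g2)
    if norm is None:
        norm = normalize_log(ds)
    X1 = np.asarray(norm[:, i1].todense())
    X2 = np.asarray(norm[:, i2].todense())
    C1 = ds.counts[:, i1]
    C2 = ds.counts[:, i2]

    pct1 = np.asarray((C1 > 0).sum(axis=1)).ravel() / len(g1)
    pct2 = np.asarray((C2 > 0).sum(axis=1)).ravel() / len(g2)
    log_fc = _log_mean_expression(X1) - _log_mean_expression(X2)
    keep = (np.maximum(pct1, pct2) > min_pct) & (np.abs(log_fc) >= min_abs_logfc)
    tested = np.flatnonzero(keep)
    if len(tested) == 0:
        return pd.DataFrame(columns=DE_COLUMNS)

    pvals = np.array([rank_sum_test(X1[g], X2[g]) for g in tested])
    padj = np.minimum(pvals * len(tested), 1.0)
    out = pd.DataFrame(
        {
            "gene_id": [ds.gene_ids[g] for g in tested],
            "log_fc": log_fc[tested],
            "pct1": pct1[tested],
            "pct2": pct2[tested],
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": padj < alpha,
        }
    )
    out = out.sort_values(
        ["p_adjusted", "log_fc"],
        key=lambda s: np.abs(s) if s.name == "log_fc" else s,
        ascending=[True, False],
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------


def build_groups(
    tm: TerritoryMap,
    mode: str,
    selection,
    cell_annotations: Mapping[str, str] | None = None,
    lm: LayerMap | None = None,
    min_cells: int = MIN_CELLS_PER_SIDE,
) -> list[GroupPair]:
    """Emit the (group1, group2) barcode-set pairs implied by a comparison mode.

    Modes
    -----
    ``vs_all``
        ``selection`` is a territory label; pair it against all other
        territories combined (isolated barcodes excluded).
    ``vs_each``
        ``selection`` is a territory label; one pair per other territory.
    ``set_vs_set``
        ``selection`` is a pair of label collections.
    ``cells_in_territories``
        ``selection`` is a pair of label collections; requires
        ``cell_annotations`` (barcode -> cell type).  One pair per cell type
        with more than ``min_cells`` annotated cells on each side; types
        below the floor are skipped with a logged notice.
    ``layer_vs_layer``
        ``selection`` is a pair of layer indices of ``lm``.
    """
    if mode == "vs_all":
        t = _single(selection)
        g1 = tm.barcodes(t)
        g2 = [b for u in tm.territories if u != t for b in tm.barcodes(u)]
        _check_nonempty(t, g1)
        return [GroupPair(f"{t}_vs_all", g1, g2)]
    if mode == "vs_each":
        t = _single(selection)
        g1 = tm.barcodes(t)
        _check_nonempty(t, g1)
        return [
            GroupPair(f"{t}_vs_{u}", g1, tm.barcodes(u))
            for u in tm.territories
            if u != t
        ]
    if mode == "set_vs_set":
        set_a, set_b = selection
        g1 = [b for t in set_a for b in tm.barcodes(t)]
        g2 = [b for t in set_b for b in tm.barcodes(t)]
        _check_nonempty(tuple(set_a), g1)
        _check_nonempty(tuple(set_b), g2)
        return [GroupPair("set_vs_set", g1, g2)]
    if mode == "cells_in_territories":
        if cell_annotations is None:
            raise ValueError("cells_in_territories requires cell annotations")
        set_a, set_b = selection
        in_a = {b for t in set_a for b in tm.barcodes(t)}
        in_b = {b for t in set_b for b in tm.barcodes(t)}
        types = sorted({ct for b, ct in cell_annotations.items() if b in in_a | in_b})
        pairs = []
        for ct in types:
            g1 = sorted(b for b in in_a if cell_annotations.get(b) == ct)
            g2 = sorted(b for b in in_b if cell_annotations.get(b) == ct)
            if len(g1) > min_cells and len(g2) > min_cells:
                pairs.append(GroupPair(f"{ct}", g1, g2))
            else:
                logger.info(
                    "cell type %s below %d-cell floor (%d vs %d); skipped",
                    ct, min_cells, len(g1), len(g2),
                )
        return pairs
    if mode == "layer_vs_layer":
        if lm is None:
            raise ValueError("layer_vs_layer requires a LayerMap")
        li, lj = selection
        g1, g2 = lm.barcodes(int(li)), lm.barcodes(int(lj))
        _check_nonempty(li, g1)
        _check_nonempty(lj, g2)
        return [GroupPair(f"layer{li}_vs_layer{lj}", g1, g2)]
    raise ValueError(f"unknown comparison mode {mode!r}")


def _single(selection):
    if isinstance(selection, (list, tuple)):
        if len(selection) != 1:
            raise ValueError("this mode takes a single territory label")
        return selection[0]
    return selection


def _check_nonempty(label, group: Sequence[str]) -> None:
    if not group:
        raise ValueError(f"selection {label!r} matches no barcode")


# ---------------------------------------------------------------------------
# visualization
# ---------------------------------------------------------------------------


def gene_image(
    ds: SpatialDataset,
    tm_or_lm: TerritoryMap | LayerMap,
    gene: str,
    tilemap: TileMap,
    norm: sp.spmatrix | None = None,
) -> ImageArray:
    """Paint a gene's normalized expression onto the territory/layer tiles.

    Per-barcode log-normalized expression (per-layer means for a
    :class:`LayerMap`) is min-max scaled over the displayed region and
    painted as a single-hue (gray) image; pixels outside the region are 0.
    """
    gi = ds.gene_index(gene)
    if norm is None:
        norm = normalize_log(ds)
    expr = np.asarray(norm[gi].todense()).ravel()

    if isinstance(tm_or_lm, LayerMap):
        region = list(tm_or_lm.layer_of)
        values = np.empty(len(region))
        layer_mean = {
            li: expr[ds.index_of(tm_or_lm.barcodes(li))].mean()
            for li in range(1, tm_or_lm.n_layers + 1)
        }
        for i, b in enumerate(region):
            values[i] = layer_mean[tm_or_lm.layer_of[b]]
    else:
        region = [b for b, v in tm_or_lm.assignment.items() if v != ISOLATED]
        values = expr[ds.index_of(region)]
    if not region:
        raise ValueError("no barcodes to display")
    scaled = minmax_channel(values)

    lookup = {b: i for i, b in enumerate(tilemap.barcode_ids)}
    intensity = np.zeros(len(tilemap.barcode_ids))
    in_region = np.zeros(len(tilemap.barcode_ids), dtype=bool)
    for b, v in zip(region, scaled):
        intensity[lookup[b]] = v
        in_region[lookup[b]] = True
    img = intensity[tilemap.owner] * in_region[tilemap.owner]
    return ImageArray(array=np.repeat(img[:, :, None], 3, axis=2), tilemap=tilemap)
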