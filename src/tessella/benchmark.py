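"""Partition scoring (ARI / VI) and the replicate benchmark harness.

Predicted territory maps are scored against simulator ground truth with the
adjusted Rand index (chance-corrected pair agreement; 1 = identical up to
relabeling) and the variation of information (VI = H(a) + H(b) - 2 I(a;b) in
nats; 0 = identical, bounded by ln n, robust to cluster granularity).
Barcodes labeled ``isolated`` are scored as one extra predicted cluster
rather than dropped, so the score covers every barcode that reached
territory isolation.

:func:`run_benchmark` runs the full embed -> image -> segment -> isolate
pipeline on each replicate of a simulated suite and tabulates per-replicate
scores; :func:`summarize_scores` reduces a score table to medians and IQRs,
and :func:`compare_score_tables` applies the replicate statistics
(Shapiro-Wilk, Bartlett, Kruskal-Wallis, pairwise rank-sum) across methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .io import ISOLATED, SpatialDataset, TerritoryMap
from .embedding import embed_dataset
from .imaging import build_image, filter_stray, tessellate
from .segmentation import SmoothingConfig, segment_iterative
from .territories import isolate_territories
from .simulator import SimulatedPuck

logger = logging.getLogger("tessella.benchmark")


@dataclass
class PartitionScore:
    ari: float
    vi: float
    n_items: int


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _check_pair(a, b, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if len(a) < min_len:
        raise ValueError(f"need at least {min_len} items")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index between two labelings."""
    a, b = _check_pair(a, b, 2)
    return float(adjusted_rand_score(a, b))


def variation_of_information(a, b) -> float:
    """Variation of information between two labelings, in nats."""
    a, b = _check_pair(a, b, 1)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    h_a = float(stats.entropy(np.bincount(ai)))
    h_b = float(stats.entropy(np.bincount(bi)))
    mi = float(mutual_info_score(ai, bi))
    vi = h_a + h_b - 2.0 * mi
    # snap float residue so identical partitions score exactly zero
    return vi if vi > 1e-12 else 0.0


def score_partitions(a, b) -> PartitionScore:
    a, b = _check_pair(a, b, 2)
    return PartitionScore(
        ari=adjusted_rand_index(a, b),
        vi=variation_of_information(a, b),
        n_items=len(a),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end territory-detection settings.

    The benchmark defaults are sized for desk-scale simulated pucks
    (~2,000-6,000 barcodes on the unit square): a 300-pixel canvas and a
    heavy Gaussian schedule (sigma 5, 10 iterations) so that blurring
    averages colors over a few tile widths — which is what lets a territory
    composed of several cell types converge to one mixed color.
    """

    embedding: str = "umap"
    n_hvg: int = 2000
    n_pcs: int = 30
    long_side: int = 300
    stray_grid: int = 50
    stray_quantile: float = 0.01
    k_sequence: list[int] = field(default_factory=lambda: [3])
    mode: str = "center_pixel"
    smoothing: SmoothingConfig = field(
        default_factory=lambda: SmoothingConfig(
            method="gaussian", size=5.0, iterations=10, equalize=True
        )
    )
    capture_prop: float = 0.05
    min_barcodes: int = 50


def run_pipeline(
    ds: SpatialDataset, cfg: PipelineConfig | None = None, seed: int = 0
) -> tuple[TerritoryMap, SpatialDataset]:
    """Run stray filter -> embedding -> image -> segmentation -> isolation.

    Returns the territory map and the stray-filtered dataset it refers to.
    """
    cfg = cfg or PipelineConfig()
    ds_f = filter_stray(ds, grid_cells=cfg.stray_grid, density_quantile=cfg.stray_quantile)
    colors = embed_dataset(
        ds_f, method=cfg.embedding, n_hvg=cfg.n_hvg, n_pcs=cfg.n_pcs, seed=seed
    )
    tm = tessellate(ds_f, long_side=cfg.long_side)
    img = build_image(tm, colors)
    ccm = segment_iterative(
        img, k_sequence=list(cfg.k_sequence), mode=cfg.mode,
        smoothing=cfg.smoothing, seed=seed,
    )
    terr = isolate_territories(
        ccm, ds_f, capture_prop=cfg.capture_prop, min_barcodes=cfg.min_barcodes
    )
    return terr, ds_f


def _labels_with_isolated(tm: TerritoryMap, barcodes) -> np.ndarray:
    """Integer labels with all isolated barcodes pooled into one extra cluster."""
    extra = max(tm.territories, default=0) + 1
    return np.array(
        [extra if tm.assignment[b] == ISOLATED else tm.assignment[b] for b in barcodes]
    )


def run_benchmark(
    suite: list[SimulatedPuck],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score the pipeline against ground truth on each replicate of a suite.

    Returns one row per replicate with columns ``replicate``, ``regime``,
    ``ari``, ``vi``, ``n``.  A replicate on which the pipeline fails is
    recorded with NaN scores rather than aborting the run.
    """
    if not suite:
        raise ValueError("empty suite")
    rows = []
    for rep, puck in enumerate(suite):
        regime = puck.config.regime
        try:
            tm, ds_f = run_pipeline(puck.dataset, cfg, seed=seed + rep)
            barcodes = [b for b in ds_f.barcode_ids if b in tm.assignment]
            pred = _labels_with_isolated(tm, barcodes)
            truth = puck.truth_labels(barcodes)
            score = score_partitions(truth, pred)
            rows.append((rep, regime, score.ari, score.vi, score.n_items))
        except Exception:
            logger.exception("pipeline failed on replicate %d", rep)
            rows.append((rep, regime, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["replicate", "regime", "ari", "vi", "n"])


def summarize_scores(scores: pd.DataFrame) -> dict[str, float]:
    """Median and IQR of ARI and VI over replicates."""
    out = {}
    for m in ("ari", "vi"):
        v = scores[m].dropna()
        out[f"median_{m}"] = float(v.median()) if len(v) else float("nan")
        out[f"iqr_{m}"] = (
            float(v.quantile(0.75) - v.quantile(0.25)) if len(v) else float("nan")
        )
    return out


def compare_score_tables(
    tables: dict[str, pd.DataFrame], metric: str = "ari"
) -> dict[str, object]:
    """Replicate statistics across methods' score tables.

    Shapiro-Wilk normality and Bartlett homogeneity per method, a global
    Kruskal-Wallis test, and pairwise two-sided rank-sum comparisons.
    """
    groups = {name: df[metric].dropna().to_numpy() for name, df in tables.items()}
    if len(groups) < 2:
        raise ValueError("need at least two score tables to compare")
    shapiro = {
        name: float(stats.shapiro(v).pvalue) if len(v) >= 3 else float("nan")
        for name, v in groups.items()
    }
    bartlett = float(stats.bartlett(*groups.values()).pvalue)
    kruskal = float(stats.kruskal(*groups.values()).pvalue)
    pairwise = {
        f"{a}_vs_{b}": float(
            stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        )
        for a, b in combinations(groups, 2)
    }
    return {
        "shapiro_p": shapiro,
        "bartlett_p": bartlett,
        "kruskal_p": kruskal,
        "pairwise_ranksum_p": pairwise,
    }
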