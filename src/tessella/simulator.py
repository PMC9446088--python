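"""Ground-truthed synthetic high-resolution ST pucks.

The simulator emulates a Slide-seq-like puck: 6,000 barcodes at uniform
random positions on the unit square, each carrying the expression profile of
a single cell type, arranged into ground-truth territories under four
regimes:

``pure``
    three equal vertical bands, one cell type per territory;
``uniform``
    three bands, each holding a different set of ``n_types`` cell types in
    equal proportion;
``exponential``
    three bands sharing the same ``n_types`` cell types in proportions
    ``P_l = e^l / sum_l e^l``, with the proportion vector cyclically shifted
    between territories so each territory has a different dominant type;
``dotted``
    a background territory with five circular territories of random center
    and radius (later disks overwrite earlier ones where they overlap), each
    territory holding 1-3 cell types in equal mixture.

Cell types draw from a pool of synthetic negative-binomial expression
profiles: each type has a disjoint block of marker genes at elevated mean,
all other genes at a shared baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import SpatialDataset

logger = logging.getLogger("tessella.simulator")

REGIMES = ("pure", "uniform", "exponential", "dotted")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated puck.

    Defaults mirror the benchmark conditions: 6,000 cells, three equal
    territories (plus background + 5 disks in the dotted regime), a pool of
    13 cell types, and 2,000-gene NB profiles with 50 five-fold markers per
    type at baseline mean 0.5 and dispersion 2.
    """

    regime: str = "uniform"
    n_cells: int = 6000
    n_territories: int = 3
    n_types: int = 3
    n_type_pool: int = 13
    seed: int = 0
    n_genes: int = 2000
    markers_per_type: int = 50
    marker_fold: float = 5.0
    base_mean: float = 0.5
    dispersion: float = 2.0
    n_dots: int = 5
    dot_radius_range: tuple[float, float] = (0.05, 0.25)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}; got {self.regime!r}")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.n_cells < self.n_territories:
            raise ValueError("need at least one cell per territory")
        if self.n_types > self.n_type_pool:
            raise ValueError("n_types cannot exceed the cell-type pool")
        if self.markers_per_type * self.n_type_pool > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")


@dataclass
class CellTypeProfiles:
    """Pool of per-type NB expression-generating distributions."""

    means: np.ndarray  # genes x types
    dispersion: float
    gene_ids: list[str]
    type_ids: list[str]
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def sample(self, type_index: int, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (n_genes, n_cells) NB count block for one cell type."""
        mu = self.means[:, type_index][:, None]
        r = self.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, np.broadcast_to(p, (len(mu), n_cells)))


@dataclass
class SimulatedPuck:
    """Synthetic dataset plus ground truth for benchmarking."""

    dataset: SpatialDataset
    truth_territory: dict[str, int]
    truth_cell_type: dict[str, str]
    config: SimulationConfig

    def truth_labels(self, barcodes=None) -> np.ndarray:
        barcodes = barcodes if barcodes is not None else self.dataset.barcode_ids
        return np.array([self.truth_territory[b] for b in barcodes])


# ---------------------------------------------------------------------------
# regime primitives
# ---------------------------------------------------------------------------


def exponential_proportions(n: int) -> np.ndarray:
    """Cell-type proportions ``P_l = e^l / sum_{l=1..n} e^l``.

    Strictly increasing in l and summing to one.
    """
    if n < 1:
        raise ValueError("need at least one cell type")
    w = np.exp(np.arange(1, n + 1, dtype=float))
    return w / w.sum()


def generate_profiles(cfg: SimulationConfig) -> CellTypeProfiles:
    """Build the synthetic NB profile pool for ``cfg.n_type_pool`` cell types.

    Type ``t`` receives the disjoint marker block
    ``genes[t*m:(t+1)*m]`` at mean ``base_mean * marker_fold``; every other
    gene sits at ``base_mean``.  Seeded (identical config -> identical pool).
    """
    m, pool = cfg.markers_per_type, cfg.n_type_pool
    gene_ids = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    type_ids = [f"type_{t + 1:02d}" for t in range(pool)]
    means = np.full((cfg.n_genes, pool), cfg.base_mean, dtype=float)
    marker_genes: dict[str, list[str]] = {}
    for t in range(pool):
        block = slice(t * m, (t + 1) * m)
        means[block, t] = cfg.base_mean * cfg.marker_fold
        marker_genes[type_ids[t]] = gene_ids[block]
    return CellTypeProfiles(
        means=means,
        dispersion=cfg.dispersion,
        gene_ids=gene_ids,
        type_ids=type_ids,
        marker_genes=marker_genes,
    )


def _assign_territories(cfg: SimulationConfig, coords: np.ndarray, rng) -> np.ndarray:
    if cfg.regime == "dotted":
        territory = np.ones(cfg.n_cells, dtype=int)  # background = 1
        for d in range(cfg.n_dots):
            center = coords[rng.integers(cfg.n_cells)]
            radius = rng.uniform(*cfg.dot_radius_range)
            inside = ((coords - center) ** 2).sum(axis=1) <= radius**2
            territory[inside] = d + 2  # later disks overwrite earlier ones
        return territory
    # three (or n) equal vertical bands over the unit square
    bands = np.floor(coords[:, 0] * cfg.n_territories).astype(int)
    return np.clip(bands, 0, cfg.n_territories - 1) + 1


def _territory_type_rules(cfg: SimulationConfig, labels: np.ndarray, rng):
    """Per-territory (type indices, proportions) according to the regime."""
    pool = np.arange(cfg.n_type_pool)
    present = sorted(np.unique(labels).tolist())
    rules: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if cfg.regime == "pure":
        chosen = rng.choice(pool, size=len(present), replace=False)
        for t, ct in zip(present, chosen):
            rules[t] = (np.array([ct]), np.array([1.0]))
    elif cfg.regime == "uniform":
        seen: set[tuple] = set()
        for t in present:
            while True:
                types = np.sort(rng.choice(pool, size=cfg.n_types, replace=False))
                if tuple(types) not in seen:
                    seen.add(tuple(types))
                    break
            rules[t] = (types, np.full(cfg.n_types, 1.0 / cfg.n_types))
    elif cfg.regime == "exponential":
        types = np.sort(rng.choice(pool, size=cfg.n_types, replace=False))
        props = exponential_proportions(cfg.n_types)
        for shift, t in enumerate(present):
            rules[t] = (types, np.roll(props, shift))
    else:  # dotted
        for t in present:
            k = rng.integers(1, 4)  # 1..3 cell types
            types = np.sort(rng.choice(pool, size=k, replace=False))
            rules[t] = (types, np.full(k, 1.0 / k))
    return rules


def simulate_puck(cfg: SimulationConfig) -> SimulatedPuck:
    """Generate one ground-truthed synthetic puck under the configured regime."""
    rng = np.random.default_rng(cfg.seed)
    coords = rng.uniform(size=(cfg.n_cells, 2))
    territory = _assign_territories(cfg, coords, rng)
    rules = _territory_type_rules(cfg, territory, rng)

    cell_type = np.empty(cfg.n_cells, dtype=int)
    for t, (types, props) in rules.items():
        members = np.flatnonzero(territory == t)
        cell_type[members] = rng.choice(types, size=len(members), p=props)

    profiles = generate_profiles(cfg)
    counts = np.empty((cfg.n_genes, cfg.n_cells), dtype=np.int64)
    for ct in np.unique(cell_type):
        members = np.flatnonzero(cell_type == ct)
        counts[:, members] = profiles.sample(int(ct), len(members), rng)

    barcode_ids = [f"bead_{i:05d}" for i in range(cfg.n_cells)]
    ds = SpatialDataset(
        barcode_ids=barcode_ids,
        coords=coords,
        counts=sp.csr_matrix(counts),
        gene_ids=profiles.gene_ids,
    )
    return SimulatedPuck(
        dataset=ds,
        truth_territory={b: int(t) for b, t in zip(barcode_ids, territory)},
        truth_cell_type={
            b: profiles.type_ids[int(ct)] for b, ct in zip(barcode_ids, cell_type)
        },
        config=cfg,
    )


def replicate_suite(cfg: SimulationConfig, n_reps: int = 10) -> list[SimulatedPuck]:
    """``n_reps`` pucks with distinct seeds derived from the master seed.

    Each replicate re-samples coordinates, cell types and counts; the whole
    suite is reproducible from ``cfg.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    seeds: list[int] = []
    while len(seeds) < n_reps:
        s = int(rng.integers(0, 2**31 - 1))
        if s not in seeds:
            seeds.append(s)
    return [simulate_puck(dataclasses.replace(cfg, seed=s)) for s in seeds]
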