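import numpy as np
import pytest
import scipy.sparse as sp

import tessella as ts


def make_grid_tilemap(h: int, w: int) -> ts.TileMap:
    """Tile map with one single-pixel tile per grid cell (row-major ids)."""
    owner = np.arange(h * w, dtype=np.int32).reshape(h, w)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    ids = [f"px_{r}_{c}" for r, c in centers]
    return ts.TileMap(owner=owner, centers=centers, barcode_ids=ids)


def make_dataset(counts: np.ndarray, coords: np.ndarray) -> ts.SpatialDataset:
    genes, n = counts.shape
    return ts.SpatialDataset(
        barcode_ids=[f"b{i}" for i in range(n)],
        coords=np.asarray(coords, dtype=float),
        counts=sp.csr_matrix(np.asarray(counts)),
        gene_ids=[f"g{i}" for i in range(genes)],
    )


@pytest.fixture(scope="session")
def small_pure_puck() -> ts.SimulatedPuck:
    """A small pure-regime puck shared by tests that only need plumbing."""
    cfg = ts.SimulationConfig(
        regime="pure",
        n_cells=300,
        n_genes=200,
        markers_per_type=10,
        n_type_pool=5,
        seed=42,
    )
    return ts.simulate_puck(cfg)


@pytest.fixture(scope="session")
def fast_pipeline_config() -> ts.PipelineConfig:
    """Cheap pipeline settings (PCA colors, small canvas) for plumbing tests."""
    return ts.PipelineConfig(
        embedding="pca",
        n_hvg=200,
        n_pcs=10,
        long_side=120,
        k_sequence=[3],
        min_barcodes=10,
    )
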