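"""Shared data model and on-disk formats.

The package operates on sequencing-based spatial transcriptomics (ST) assays
— Slide-seq, Seq-Scope, Visium and the like — where every barcode (bead/spot)
carries a gene-count vector and an (x, y) coordinate in assay units.  The
universal in-memory container is :class:`SpatialDataset`; territory calls are
carried by :class:`TerritoryMap`.

Supported inputs are the 10x-style Matrix Market triplet (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``) or a dense CSV with genes as rows, plus a
coordinate table with columns ``barcode``, ``x``, ``y``.  Outputs are plain
TSV (territories, colors, tile maps) and 8-bit PNG/TIFF images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("tessella.io")

#: Sentinel territory label for barcodes in groups too small to be territories.
ISOLATED = "isolated"


class FormatError(ValueError):
    """An input file does not conform to the expected format."""


class EmptyIntersectionError(ValueError):
    """Counts and coordinates share no barcode."""


class ConsistencyError(ValueError):
    """Objects that must refer to the same barcodes do not."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialDataset:
    """A gene x barcode count matrix with per-barcode 2-D coordinates.

    Parameters
    ----------
    barcode_ids
        Unique barcode identifiers, one per spatial capture unit.
    coords
        ``(n_barcodes, 2)`` float array of (x, y) positions in assay units.
    counts
        Sparse non-negative count matrix, genes x barcodes.
    gene_ids
        Unique gene identifiers, one per count-matrix row.
    """

    barcode_ids: list[str]
    coords: np.ndarray
    counts: sp.csr_matrix
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.barcode_ids = list(self.barcode_ids)
        self.gene_ids = list(self.gene_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        n, g = len(self.barcode_ids), len(self.gene_ids)
        if self.coords.shape != (n, 2):
            raise ConsistencyError(
                f"coords shape {self.coords.shape} != ({n}, 2)"
            )
        if self.counts.shape != (g, n):
            raise ConsistencyError(
                f"counts shape {self.counts.shape} != ({g}, {n})"
            )
        if len(set(self.barcode_ids)) != n:
            raise ConsistencyError("duplicate barcode identifiers")
        if len(set(self.gene_ids)) != g:
            raise ConsistencyError("duplicate gene identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        self._index: dict[str, int] = {b: i for i, b in enumerate(self.barcode_ids)}

    # -- convenience ------------------------------------------------------

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, barcodes: Iterable[str]) -> np.ndarray:
        """Positional indices of the given barcodes (KeyError if unknown)."""
        return np.array([self._index[b] for b in barcodes], dtype=int)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_barcodes(self, idx: np.ndarray | Sequence[int]) -> "SpatialDataset":
        """New dataset restricted to the given barcode positions, in order."""
        idx = np.asarray(idx, dtype=int)
        return SpatialDataset(
            barcode_ids=[self.barcode_ids[i] for i in idx],
            coords=self.coords[idx],
            counts=self.counts[:, idx].tocsr(),
            gene_ids=list(self.gene_ids),
        )


@dataclass
class TerritoryMap:
    """Per-barcode territory assignment.

    Labels are contiguous positive integers ``1..T`` plus the sentinel
    :data:`ISOLATED` for barcodes in groups too small (or too remote) to be
    called territories.
    """

    assignment: dict[str, int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = sorted(
            {v for v in self.assignment.values() if v != ISOLATED}
        )
        for v in labels:
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"territory label must be >=1 or {ISOLATED!r}: {v!r}")
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"territory labels not contiguous 1..T: {labels}")

    @property
    def territories(self) -> list[int]:
        """Sorted list of (non-isolated) territory labels."""
        return sorted({v for v in self.assignment.values() if v != ISOLATED})

    def barcodes(self, label: int | str) -> list[str]:
        return [b for b, v in self.assignment.items() if v == label]

    def labels_for(self, barcodes: Iterable[str]) -> list[int | str]:
        return [self.assignment[b] for b in barcodes]

    def __eq__(self, other: object) -> bool:  # value semantics for round-trips
        return isinstance(other, TerritoryMap) and self.assignment == other.assignment


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    # sniff TSV vs CSV; both occur in the wild for coordinate files
    return pd.read_csv(path, sep=None, engine="python")


def _read_coords(coords_path: Path) -> pd.DataFrame:
    df = _read_table(coords_path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"barcode", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"coordinate table must have columns barcode, x, y; got {list(df.columns)}"
        )
    df["barcode"] = df["barcode"].astype(str)
    if df["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes in coordinate table")
    return df[["barcode", "x", "y"]]


def read_spatial_counts(
    counts_path: str | Path,
    coords_path: str | Path,
    format: str = "mtx_triplet",
    barcodes_path: str | Path | None = None,
    features_path: str | Path | None = None,
    drop_zero_barcodes: bool = True,
) -> SpatialDataset:
    """Load counts + coordinates into a :class:`SpatialDataset`.

    The returned dataset is restricted to barcodes present in *both* files,
    in coordinate-file order; barcodes present on only one side are dropped
    with a logged warning.  Gene order follows the counts file.  Barcodes with
    zero total counts are dropped (undefined under log-normalization).

    Parameters
    ----------
    counts_path
        ``.mtx`` file (``mtx_triplet``) or dense CSV with genes as rows and a
        leading gene-id column (``dense_csv``).
    coords_path
        TSV/CSV with columns ``barcode``, ``x``, ``y``.
    format
        ``"mtx_triplet"`` or ``"dense_csv"``.
    barcodes_path, features_path
        Sidecar files for the MTX triplet; default to ``barcodes.tsv`` and
        ``features.tsv`` next to the matrix.
    """
    counts_path = Path(counts_path)
    coords_path = Path(coords_path)
    if format == "mtx_triplet":
        bpath = Path(barcodes_path) if barcodes_path else _sidecar(counts_path, "barcodes.tsv")
        fpath = Path(features_path) if features_path else _sidecar(counts_path, "features.tsv")
        try:
            mat = sp.csr_matrix(mmread(counts_path))
        except Exception as exc:  # malformed header/body
            raise FormatError(f"cannot parse Matrix Market file {counts_path}: {exc}") from exc
        barcodes = [ln.split("\t")[0] for ln in _read_lines(bpath)]
        genes = [ln.split("\t")[0] for ln in _read_lines(fpath)]
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match features x barcodes "
                f"({len(genes)} x {len(barcodes)})"
            )
    elif format == "dense_csv":
        try:
            df = pd.read_csv(counts_path, index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse dense counts CSV {counts_path}: {exc}") from exc
        genes = [str(g) for g in df.index]
        barcodes = [str(b) for b in df.columns]
        mat = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown format {format!r}")

    if mat.nnz and mat.data.min() < 0:
        raise FormatError("count matrix contains negative entries")

    coords = _read_coords(coords_path)
    count_index = {b: i for i, b in enumerate(barcodes)}
    keep = coords["barcode"].isin(count_index).to_numpy()
    if not keep.any():
        raise EmptyIntersectionError("no barcode shared between counts and coordinates")
    n_coord_only = int((~keep).sum())
    if n_coord_only:
        logger.warning("%d coordinate barcodes absent from counts; dropped", n_coord_only)
    coords = coords.loc[keep]
    order = [count_index[b] for b in coords["barcode"]]
    n_count_only = len(barcodes) - len(order)
    if n_count_only:
        logger.warning("%d count barcodes absent from coordinates; dropped", n_count_only)

    ds = SpatialDataset(
        barcode_ids=list(coords["barcode"]),
        coords=coords[["x", "y"]].to_numpy(dtype=float),
        counts=mat[:, order].tocsr(),
        gene_ids=genes,
    )
    if drop_zero_barcodes:
        totals = np.asarray(ds.counts.sum(axis=0)).ravel()
        if (totals == 0).any():
            nz = np.flatnonzero(totals > 0)
            logger.warning(
                "%d barcodes with zero total counts dropped", ds.n_barcodes - len(nz)
            )
            if len(nz) == 0:
                raise EmptyIntersectionError("all barcodes have zero total counts")
            ds = ds.subset_barcodes(nz)
    return ds


def _sidecar(counts_path: Path, name: str) -> Path:
    """Resolve a triplet sidecar: plain name, or prefixed like the matrix."""
    plain = counts_path.parent / name
    if plain.exists():
        return plain
    if counts_path.name.endswith("matrix.mtx"):
        prefixed = counts_path.parent / (
            counts_path.name[: -len("matrix.mtx")] + name
        )
        if prefixed.exists():
            return prefixed
    return plain


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file {path}")
    return [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]


# ---------------------------------------------------------------------------
# writers / round-trips
# ---------------------------------------------------------------------------


def write_territories(tm: TerritoryMap, ds: SpatialDataset, path: str | Path) -> None:
    """Write a territory map to TSV (barcode, x, y, territory).

    Barcodes are written in dataset order; every labeled barcode must exist in
    ``ds``.  The :data:`ISOLATED` sentinel is written verbatim.
    """
    unknown = [b for b in tm.assignment if b not in ds._index]
    if unknown:
        raise ConsistencyError(f"territory map references unknown barcodes: {unknown[:5]}")
    rows = []
    for b in ds.barcode_ids:
        if b in tm.assignment:
            i = ds._index[b]
            rows.append((b, ds.coords[i, 0], ds.coords[i, 1], tm.assignment[b]))
    pd.DataFrame(rows, columns=["barcode", "x", "y", "territory"]).to_csv(
        path, sep="\t", index=False
    )


def read_territories(path: str | Path) -> TerritoryMap:
    """Read a territory TSV written by :func:`write_territories`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "territory": str})
    if not {"barcode", "territory"}.issubset(df.columns):
        raise FormatError("territory file must have columns barcode, territory")
    assignment: dict[str, int | str] = {}
    for b, t in zip(df["barcode"], df["territory"]):
        assignment[b] = ISOLATED if t == ISOLATED else int(t)
    return TerritoryMap(assignment)


def write_spatial_dataset(ds: SpatialDataset, prefix: str | Path) -> None:
    """Serialize a dataset as ``{prefix}_matrix.mtx`` + barcode/feature/coord TSVs."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    counts = ds.counts.tocoo()
    field_kind = "integer" if np.issubdtype(counts.dtype, np.integer) else "real"
    mmwrite(str(prefix) + "_matrix.mtx", counts, field=field_kind)
    Path(str(prefix) + "_barcodes.tsv").write_text("\n".join(ds.barcode_ids) + "\n")
    Path(str(prefix) + "_features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    pd.DataFrame(
        {"barcode": ds.barcode_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    ).to_csv(str(prefix) + "_coords.tsv", sep="\t", index=False)


def read_spatial_dataset(prefix: str | Path, **kwargs) -> SpatialDataset:
    """Inverse of :func:`write_spatial_dataset`."""
    prefix = str(prefix)
    return read_spatial_counts(
        prefix + "_matrix.mtx",
        prefix + "_coords.tsv",
        format="mtx_triplet",
        barcodes_path=prefix + "_barcodes.tsv",
        features_path=prefix + "_features.tsv",
        **kwargs,
    )


def write_colors(barcode_ids: Sequence[str], rgb: np.ndarray, path: str | Path) -> None:
    """Write per-barcode RGB triples as TSV (barcode, r, g, b)."""
    rgb = np.asarray(rgb, dtype=float)
    pd.DataFrame(
        {"barcode": list(barcode_ids), "r": rgb[:, 0], "g": rgb[:, 1], "b": rgb[:, 2]}
    ).to_csv(path, sep="\t", index=False)


def read_colors(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return list(df["barcode"]), df[["r", "g", "b"]].to_numpy(dtype=float)


def write_image(array: np.ndarray, path: str | Path) -> None:
    """Write an H x W x 3 array of values in [0, 1] as an 8-bit image."""
    import imageio.v3 as iio

    arr8 = np.clip(np.rint(np.asarray(array) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr8)
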