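"""Connectivity-matrix containers, validation and file I/O.

A structural connectome is held as a symmetric nonnegative ``n x n``
matrix with a declared *role*: raw streamline counts (NoS), fractional
anisotropy (FA), min-max normalized FA, or the fused NoS-FA weights that
the hub-location method operates on.  Diagonals are stored as zero
throughout: self-connection is treated as undefined and every downstream
formula excludes ``i == j`` explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixRole",
    "ConnectivityMatrix",
    "WeightedBrainGraph",
    "DimensionError",
    "IntegrityError",
    "EmptyNetworkError",
    "validate_and_symmetrize",
    "read_matrix",
    "write_matrix",
    "read_region_labels",
    "default_region_ids",
    "export_graphml",
]


class MatrixRole(str, Enum):
    """What the entries of a connectivity matrix mean."""

    NOS = "NoS"
    FA = "FA"
    FA_NORMALIZED = "FA_normalized"
    NOSFA = "NoSFA"


class DimensionError(ValueError):
    """Matrix shapes or region sets do not agree."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (asymmetry, negative weight)."""


class EmptyNetworkError(ValueError):
    """An operation that needs at least one edge received none."""


def default_region_ids(n: int) -> list[str]:
    """Placeholder region names R001..Rnnn used when no label file is given."""
    width = max(3, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A symmetric nonnegative region-by-region connectivity matrix.

    Parameters
    ----------
    values
        ``n x n`` symmetric matrix, zero diagonal, all entries >= 0.
        FA-role matrices must additionally have entries <= 1.
    role
        Semantic role of the entries.
    region_ids
        Ordered region identifiers, one per row/column.
    """

    values: np.ndarray
    role: MatrixRole
    region_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DimensionError(f"expected a square matrix, got shape {values.shape}")
        n = values.shape[0]
        if n < 2:
            raise DimensionError("a connectivity matrix needs at least 2 regions")
        if not np.allclose(values, values.T, rtol=0.0, atol=0.0):
            raise IntegrityError(
                "matrix is not exactly symmetric; use validate_and_symmetrize() "
                "to average small asymmetries"
            )
        if np.any(values < 0):
            raise IntegrityError("negative entries are not allowed")
        if np.any(np.diag(values) != 0):
            raise IntegrityError("diagonal must be stored as 0")
        if self.role in (MatrixRole.FA, MatrixRole.FA_NORMALIZED) and np.any(values > 1):
            raise IntegrityError(f"{self.role.value} entries must lie in [0, 1]")
        region_ids = tuple(self.region_ids) if self.region_ids else tuple(default_region_ids(n))
        if len(region_ids) != n:
            raise DimensionError(
                f"{len(region_ids)} region ids for a {n}x{n} matrix"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_ids", region_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def same_regions(self, other: "ConnectivityMatrix") -> bool:
        return self.values.shape == other.values.shape and self.region_ids == other.region_ids

    def with_values(self, values: np.ndarray, role: MatrixRole) -> "ConnectivityMatrix":
        return ConnectivityMatrix(values=values, role=role, region_ids=self.region_ids)


@dataclass(frozen=True)
class WeightedBrainGraph:
    """Weighted undirected brain graph built from a connectivity matrix.

    ``n`` is fixed at construction and never changes: the node-removal
    convention used by the vulnerability analysis zeroes a region's
    incident edges but keeps the region as an isolated node.
    """

    matrix: ConnectivityMatrix

    @property
    def weights(self) -> np.ndarray:
        return self.matrix.values

    @property
    def n(self) -> int:
        return self.matrix.n

    @property
    def region_ids(self) -> tuple[str, ...]:
        return self.matrix.region_ids

    @property
    def adjacency(self) -> np.ndarray:
        """Binary indicator a_ij = 1 iff w_ij > 0 and i != j."""
        return (self.weights > 0).astype(int)

    @property
    def m(self) -> int:
        """Number of edges (unordered pairs with positive weight)."""
        return int(np.count_nonzero(np.triu(self.weights, k=1) > 0))

    @classmethod
    def from_matrix(cls, matrix: ConnectivityMatrix) -> "WeightedBrainGraph":
        return cls(matrix=matrix)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        region_ids: Sequence[str] | None = None,
        role: MatrixRole = MatrixRole.NOSFA,
    ) -> "WeightedBrainGraph":
        cm = ConnectivityMatrix(
            values=np.asarray(values, dtype=float),
            role=role,
            region_ids=tuple(region_ids) if region_ids is not None else (),
        )
        return cls(matrix=cm)


def validate_and_symmetrize(
    values: np.ndarray,
    tolerance: float = 1e-8,
    role: MatrixRole = MatrixRole.NOS,
    region_ids: Sequence[str] | None = None,
) -> tuple[ConnectivityMatrix, int]:
    """Check a raw square matrix and return its symmetrized form.

    Asymmetries up to ``tolerance`` (relative to the largest magnitude in
    the matrix, with a floor of 1) are averaged away as ``(M + M.T) / 2``;
    anything larger is an integrity error.  The diagonal is forced to 0.

    Returns
    -------
    (matrix, n_adjusted)
        The validated matrix and the number of off-diagonal entries that
        were adjusted (asymmetric pairs count both entries).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {values.shape}")
    if np.any(values < 0):
        raise IntegrityError("negative entries are not allowed")
    scale = max(1.0, float(np.max(np.abs(values))) if values.size else 1.0)
    asym = np.abs(values - values.T)
    max_asym = float(asym.max()) if asym.size else 0.0
    if max_asym > tolerance * scale:
        raise IntegrityError(
            f"matrix asymmetry {max_asym:.3g} exceeds tolerance "
            f"{tolerance * scale:.3g}; refusing to symmetrize"
        )
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    off_diag = ~np.eye(values.shape[0], dtype=bool)
    n_adjusted = int(np.count_nonzero((asym > 0) & off_diag))
    if n_adjusted:
        logger.warning("symmetrization adjusted %d off-diagonal entries", n_adjusted)
    cm = ConnectivityMatrix(
        values=sym,
        role=role,
        region_ids=tuple(region_ids) if region_ids is not None else (),
    )
    return cm, n_adjusted


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(
    path: str | Path,
    role: MatrixRole = MatrixRole.NOS,
    region_ids: Sequence[str] | None = None,
    tolerance: float = 1e-8,
) -> ConnectivityMatrix:
    """Read an ``n x n`` matrix from delimited text (CSV or TSV).

    A single header row of column names is tolerated and ignored; row and
    column order must match the region-label file.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        values = np.loadtxt(path, delimiter=sep, ndmin=2)
    except ValueError:
        values = np.loadtxt(path, delimiter=sep, skiprows=1, ndmin=2)
    cm, _ = validate_and_symmetrize(values, tolerance=tolerance, role=role, region_ids=region_ids)
    return cm


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> None:
    """Write a matrix as headerless delimited text (delimiter from suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    np.savetxt(path, matrix.values, delimiter=sep, fmt="%.17g")


def read_region_labels(path: str | Path) -> pd.DataFrame:
    """Read a region-label table (TSV/CSV).

    Expected columns: 1-based ``index``, ``abbreviation``, optional
    ``name``; a header row is optional.  Returns a DataFrame sorted by
    index with those columns.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    # drop a header row if the first cell is not an integer
    try:
        int(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    cols = ["index", "abbreviation", "name"][: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["index"] = df["index"].astype(int)
    if "name" not in df.columns:
        df["name"] = df["abbreviation"]
    return df.sort_values("index").reset_index(drop=True)


def export_graphml(path: str | Path, graph: WeightedBrainGraph) -> None:
    """Export the weighted graph to GraphML with an edge ``weight`` attribute."""
    g = nx.Graph()
    for rid in graph.region_ids:
        g.add_node(rid)
    w = graph.weights
    ids = graph.region_ids
    for i, j in zip(*np.nonzero(np.triu(w, k=1))):
        g.add_edge(ids[i], ids[j], weight=float(w[i, j]))
    nx.write_graphml(g, str(path))
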