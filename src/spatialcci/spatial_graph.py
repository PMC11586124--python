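"""Spatial cell graphs: Euclidean kNN adjacency in 2D/3D and GCN normalization.

In solid tissue a cell is assumed to interact with the handful of cells it
physically touches, so the cell-level interaction graph is taken to be the
symmetrized k-nearest-neighbor graph of the spatial coordinates. The default
k of 6 reflects the assumption that most cells directly contact at least a
few neighbors in a 2D section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist

DEFAULT_N_NEIGHBORS = 6


@dataclass
class SpatialCoords:
    """Per-cell spatial coordinates (2D or 3D) with optional slice labels."""

    coords: np.ndarray
    cell_ids: list[str]
    layer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be an (n, 2) or (n, 3) array")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match coords")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids contain duplicates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.layer is not None:
            self.layer = np.asarray(self.layer)
            if self.layer.shape[0] != self.coords.shape[0]:
                raise ValueError("layer labels length does not match coords")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_csv(cls, path) -> "SpatialCoords":
        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        layer = df["layer"].to_numpy() if "layer" in df.columns else None
        return cls(df[cols].to_numpy(float), list(df["cell_id"].astype(str)), layer)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.coords, columns=["x", "y", "z"][: self.dim])
        df.insert(0, "cell_id", self.cell_ids)
        if self.layer is not None:
            df["layer"] = self.layer
        df.to_csv(path, index=False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Euclidean distance matrix with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Adjacency:
    """Binary symmetric adjacency matrix A with zero diagonal.

    Exposes the GCN views: A-tilde = A + I (self-loops), its degree matrix
    D-tilde, and the symmetric normalization
    A-hat = D-tilde^{-1/2} (A + I) D-tilde^{-1/2}.
    """

    matrix: np.ndarray
    node_ids: list[str] | None = None
    edge_layers: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.matrix = self.matrix.astype(float)
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(n)]
        elif len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2

    @property
    def with_self_loops(self) -> np.ndarray:
        return self.matrix + np.eye(self.n_nodes)

    @property
    def degrees(self) -> np.ndarray:
        """Diagonal of D-tilde, i.e. degree including the self-loop."""
        return self.with_self_loops.sum(axis=1)

    @property
    def normalized(self) -> np.ndarray:
        return normalize_adjacency(self)

    def edge_list(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.matrix, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def to_edge_tsv(self, path) -> None:
        rows = [(self.node_ids[i], self.node_ids[j]) for i, j in self.edge_list()]
        pd.DataFrame(rows, columns=["node_i", "node_j"]).to_csv(path, sep="\t", index=False)

    def to_mtx(self, path) -> None:
        mmwrite(str(path), coo_matrix(self.matrix))


def euclidean_distance_matrix(coords: SpatialCoords) -> DistanceMatrix:
    """Pairwise Euclidean distances D_ij = ||x_i - x_j||."""
    D = cdist(coords.coords, coords.coords)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D)


def knn_adjacency(D: DistanceMatrix, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> Adjacency:
    """Symmetrized k-nearest-neighbor graph from a distance matrix.

    For each node the ``n_neighbors`` smallest off-diagonal entries of its
    distance row define the directed neighbor set N_i; the returned matrix is
    the logical OR of that relation and its transpose. Ties at the k-th
    distance break by node index (stable argsort), so grids are deterministic.
    """
    n = D.values.shape[0]
    if not 0 < n_neighbors < n:
        raise ValueError(f"n_neighbors must be in [1, {n - 1}], got {n_neighbors}")
    A = np.zeros((n, n))
    work = D.values.astype(float).copy()
    np.fill_diagonal(work, np.inf)  # self never its own neighbor
    order = np.argsort(work, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), n_neighbors)
    A[rows, order[:, :n_neighbors].ravel()] = 1
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0)
    return Adjacency(A)


def normalize_adjacency(A: Adjacency) -> np.ndarray:
    """Symmetric GCN normalization D-tilde^{-1/2} (A + I) D-tilde^{-1/2}."""
    at = A.with_self_loops
    d_inv_sqrt = 1.0 / np.sqrt(at.sum(axis=1))
    return at * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def cross_layer_graph(coords3d: SpatialCoords, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> Adjacency:
    """kNN adjacency over stacked 3D coordinates, annotating each edge as
    intra- or inter-layer.

    The returned Adjacency carries an ``edge_layers`` frame with one row per
    undirected edge (node_i, node_j, layer_i, layer_j, inter_layer).
    """
    if coords3d.dim != 3:
        raise ValueError("cross_layer_graph requires 3D coordinates")
    if coords3d.layer is None:
        raise ValueError("cross_layer_graph requires per-cell layer labels")
    adj = knn_adjacency(euclidean_distance_matrix(coords3d), n_neighbors)
    adj.node_ids = list(coords3d.cell_ids)
    rows = []
    for i, j in adj.edge_list():
        li, lj = coords3d.layer[i], coords3d.layer[j]
        rows.append((coords3d.cell_ids[i], coords3d.cell_ids[j], li, lj, li != lj))
    adj.edge_layers = pd.DataFrame(
        rows, columns=["node_i", "node_j", "layer_i", "layer_j", "inter_layer"]
    )
    return adj
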