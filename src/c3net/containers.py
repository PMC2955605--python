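"""Core data containers shared across the package.

All containers are thin, validated wrappers around numpy arrays keyed by a
shared list of gene identifiers.  Networks are undirected and stored as
symmetric binary adjacency matrices with a zero diagonal; an edge-list view
(sorted unordered pairs) is derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "MIMatrix",
    "ConnectivityMatrix",
    "Network",
    "ScoredNetwork",
]


def _check_gene_ids(gene_ids: list[str], n: int) -> list[str]:
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != n:
        raise ValueError(f"{len(gene_ids)} gene ids for {n} rows")
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")
    return gene_ids


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples expression table.

    Rows are genes (identified by ``gene_ids``), columns are samples.
    Requires at least 2 genes, 3 samples and finite values.
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 genes")
        if m < 3:
            raise ValueError("need at least 3 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self.gene_ids = _check_gene_ids(self.gene_ids, n)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _check_square_symmetric(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(values, values.T, equal_nan=False):
        raise ValueError(f"{name} must be symmetric")
    return values


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual-information matrix.

    The diagonal is stored as zero by convention and never consulted:
    every downstream neighborhood excludes self-pairs.  ``units`` records
    the log base of the estimator ("nats" for the Gaussian estimator,
    "bits" for the B-spline estimator).
    """

    gene_ids: list[str]
    values: np.ndarray
    units: str = "nats"

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values, "MI matrix")
        off = self.values[~np.eye(len(self.values), dtype=bool)]
        if off.size and off.min() < -1e-9:
            raise ValueError("off-diagonal MI values must be nonnegative")
        np.fill_diagonal(self.values, 0.0)
        self.gene_ids = _check_gene_ids(self.gene_ids, self.values.shape[0])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Binary symmetric significance mask C: C[i, j] = 1 iff the pairwise
    MI of genes i and j passed the significance test.  Zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = _check_square_symmetric(self.values, "connectivity matrix")
        if not np.all(np.isin(values, (0.0, 1.0))):
            raise ValueError("connectivity entries must be 0 or 1")
        self.values = values.astype(np.int8)
        np.fill_diagonal(self.values, 0)
        self.gene_ids = _check_gene_ids(self.gene_ids, self.values.shape[0])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def neighborhood(self, i: int) -> np.ndarray:
        """Indices of the significant neighbors of gene ``i`` (excluding i)."""
        return np.flatnonzero(self.values[i])


@dataclass
class Network:
    """Undirected network as a symmetric binary adjacency with zero diagonal."""

    gene_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = _check_square_symmetric(self.adjacency, "adjacency")
        if not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = adj.astype(np.int8)
        np.fill_diagonal(self.adjacency, 0)
        self.gene_ids = _check_gene_ids(self.gene_ids, self.adjacency.shape[0])

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_indices(self) -> set[tuple[int, int]]:
        """Edges as a set of (i, j) index pairs with i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(ii.tolist(), jj.tolist()))

    def edges(self) -> list[tuple[str, str]]:
        """Edges as lexicographically sorted unordered gene-id pairs."""
        out = []
        for i, j in self.edge_indices():
            a, b = sorted((self.gene_ids[i], self.gene_ids[j]))
            out.append((a, b))
        return sorted(out)

    @classmethod
    def from_edge_indices(
        cls, gene_ids: list[str], pairs: "set[tuple[int, int]] | list[tuple[int, int]]"
    ) -> "Network":
        n = len(gene_ids)
        adj = np.zeros((n, n), dtype=np.int8)
        for i, j in pairs:
            if i == j:
                continue
            adj[i, j] = adj[j, i] = 1
        return cls(gene_ids, adj)

    @classmethod
    def empty(cls, gene_ids: list[str]) -> "Network":
        n = len(gene_ids)
        return cls(gene_ids, np.zeros((n, n), dtype=np.int8))


@dataclass
class ScoredNetwork:
    """Symmetric nonnegative edge-score matrix (method-specific weights).

    The binary network at a threshold t contains the pairs with
    ``weights > t``; scores of exactly zero never form edges.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _check_square_symmetric(self.weights, "weights")
        if self.weights[~np.eye(len(self.weights), dtype=bool)].min(initial=0.0) < -1e-9:
            raise ValueError("edge scores must be nonnegative")
        self.weights = np.clip(self.weights, 0.0, None)
        np.fill_diagonal(self.weights, 0.0)
        self.gene_ids = _check_gene_ids(self.gene_ids, self.weights.shape[0])

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    def threshold(self, t: float) -> Network:
        """Binary network keeping pairs with weight strictly above ``t``."""
        adj = (self.weights > t).astype(np.int8)
        np.fill_diagonal(adj, 0)
        return Network(self.gene_ids, adj)
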