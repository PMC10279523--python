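"""Per-omics kNN graphs, renormalized propagation operators, indicators.

Each omics layer gets a binary k-nearest-neighbour graph A over its samples
(an edge when either endpoint is among the other's k nearest by Euclidean
distance), the renormalized propagation operator D^{-1/2}(A+I)D^{-1/2} used
by the graph-convolutional layers, and a binary indicator matrix G mapping
the omics' local row order to positions in the intact patient universe —
the device that lets partial cohorts (patients missing one omics) share a
consensus embedding without imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class AdjacencyGraph:
    """Binary symmetric kNN adjacency with zero diagonal."""

    adj: np.ndarray
    k: int


@dataclass
class NormalizedOperator:
    """Symmetric renormalized operator D^{-1/2}(A+I)D^{-1/2}."""

    op: np.ndarray


@dataclass
class IndicatorMatrix:
    """Binary N_v x N matrix: mat[i, j] = 1 iff row_ids[i] == col_ids[j]."""

    mat: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    @property
    def indices(self) -> np.ndarray:
        """Column index of the single 1 in each row (exact G·H == H[indices])."""
        return np.argmax(self.mat, axis=1)


def default_k(n_samples: int) -> int:
    """Neighbour count: ceil(log2(N)) + 1, clamped to [2, N-1].

    A slowly growing default keeps the graph sparse yet (empirically)
    connected on cohorts of a few hundred samples.
    """
    if n_samples < 2:
        raise ValueError(f"need at least 2 samples, got {n_samples}")
    k = int(math.ceil(math.log2(n_samples))) + 1
    return max(1, min(max(2, k), n_samples - 1))


def knn_or_adjacency(dist: np.ndarray, k: int) -> np.ndarray:
    """Binary adjacency from a distance matrix under the OR rule.

    A[i, j] = 1 iff i is among the k nearest of j or j among the k nearest
    of i; self excluded; ties at the k-th distance broken by lower index
    (stable argsort), making the graph deterministic.
    """
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nearest = np.argsort(d, axis=0, kind="stable")[:k, :]  # k nearest of each column
    member = np.zeros((n, n), dtype=np.int8)
    member[nearest, np.arange(n)[None, :]] = 1  # member[i, j]: i in NN_k(j)
    adj = np.maximum(member, member.T)
    np.fill_diagonal(adj, 0)
    return adj


def build_knn_graph(x: np.ndarray, k: int) -> AdjacencyGraph:
    """Construct the binary kNN similarity graph of the rows of ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input matrix contains non-finite values")
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    dist = squareform(pdist(x, metric="euclidean"))
    return AdjacencyGraph(adj=knn_or_adjacency(dist, k), k=k)


def normalize_adjacency(g: AdjacencyGraph) -> NormalizedOperator:
    """Renormalized propagation operator D^{-1/2}(A+I)D^{-1/2}.

    D is the diagonal degree of A+I, so every degree is >= 1 and the
    operator is well defined even for isolated nodes (whose row reduces to
    a 1 on the diagonal). Its spectral radius is at most 1.
    """
    a_prime = g.adj.astype(float) + np.eye(g.adj.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_prime.sum(axis=1))
    op = a_prime * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedOperator(op=op)


def build_indicator_matrix(
    omics_ids: Sequence[str], intact_ids: Sequence[str]
) -> IndicatorMatrix:
    """Binary indicator mapping omics-local rows to intact-cohort columns."""
    omics_ids = list(omics_ids)
    intact_ids = list(intact_ids)
    for name, ids in (("omics_ids", omics_ids), ("intact_ids", intact_ids)):
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate ID {dup!r} in {name}")
    col_index = {sid: j for j, sid in enumerate(intact_ids)}
    mat = np.zeros((len(omics_ids), len(intact_ids)), dtype=np.int8)
    for i, sid in enumerate(omics_ids):
        if sid not in col_index:
            raise ValueError(f"omics sample ID {sid!r} not found in intact_ids")
        mat[i, col_index[sid]] = 1
    return IndicatorMatrix(mat=mat, row_ids=omics_ids, col_ids=intact_ids)


def write_edge_list(g: AdjacencyGraph, path) -> None:
    """Serialize the upper-triangle edges as TSV with a ``# k=...`` header."""
    i, j = np.nonzero(np.triu(g.adj, k=1))
    with open(path, "w") as fh:
        fh.write(f"# k={g.k}\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\n")
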