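"""Hybrid spatial+expression graphs, Leiden domains, and label transfer.

Whole tissue sections are clustered on a graph that blends transcriptomic
similarity with physical proximity: a kNN graph is built in expression
(PC) space and another in spatial coordinates, edge weights come from a
shared-neighbour kernel, and the hybrid weight is the convex combination
``blend * expression + (1 - blend) * spatial`` on the union of edge sets
(equal weighting by default). Communities are found by Leiden modularity
optimization with a mandatory seed.

Cross-modality annotation uses kNN label transfer in a shared embedding:
each query cell takes the modal label of its k nearest reference cells,
abstaining ("NA") when its k nearest neighbours in the joint
reference+query pool contain too few reference cells — the signature of a
failed integration for that cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError

__all__ = ["HybridGraph", "build_hybrid_graph", "cluster_domains", "transfer_labels"]


@dataclass
class HybridGraph:
    """Symmetric weighted graph over cells with a record of the blend."""

    weights: sp.csr_matrix  # symmetric, zero diagonal
    blend_weight: float
    n_neighbors: int
    cell_ids: np.ndarray | None = None


def _shared_neighbor_weights(emb: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric kNN graph with shared-neighbour kernel weights.

    Edge (i, j) exists when either cell is among the other's k nearest
    neighbours; its weight is ``(1 + |N(i) & N(j)|) / (1 + k)`` so that
    every kNN edge has positive weight and edges between cells with many
    common neighbours are strong.
    """
    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    A = nn.kneighbors_graph(emb, mode="connectivity")  # includes self
    A = A - sp.eye(n, format="csr")
    A.eliminate_zeros()
    union = ((A + A.T) > 0).astype(float)
    shared = (A @ A.T).toarray() if n <= 4096 else (A @ A.T)
    W = union.multiply(1.0 / (1.0 + k)) + union.multiply(shared) * (1.0 / (1.0 + k))
    W = sp.csr_matrix(W)
    W.setdiag(0.0)
    W.eliminate_zeros()
    return W


def build_hybrid_graph(
    expr_embedding: np.ndarray,
    coords: np.ndarray,
    k: int = 15,
    blend_weight: float = 0.5,
) -> HybridGraph:
    """Blend expression-space and physical-space kNN graphs.

    ``blend_weight = 1`` reproduces the expression graph exactly and ``0``
    the spatial graph; the default 0.5 weights the two equally. Edge weights
    on the union of edge sets are the convex combination of the two
    per-modality shared-neighbour weights (0 where a modality lacks the
    edge).
    """
    expr_embedding = np.asarray(expr_embedding, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = expr_embedding.shape[0]
    if coords.shape[0] != n:
        raise ConfigError("expression embedding and coordinates must cover the same cells")
    if k >= n:
        raise ConfigError("k must be smaller than the number of cells")
    if not 0.0 <= blend_weight <= 1.0:
        raise ConfigError("blend_weight must lie in [0, 1]")
    W_expr = _shared_neighbor_weights(expr_embedding, k)
    W_spat = _shared_neighbor_weights(coords, k)
    W = blend_weight * W_expr + (1.0 - blend_weight) * W_spat
    W = sp.csr_matrix(W)
    W.eliminate_zeros()
    return HybridGraph(weights=W, blend_weight=blend_weight, n_neighbors=k)


def cluster_domains(g: HybridGraph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community labels on the hybrid graph (deterministic per seed)."""
    W = sp.coo_matrix(sp.triu(g.weights, k=1))
    if W.shape[0] == 0 or W.nnz == 0:
        raise DataError("empty graph")
    graph = igraph.Graph(
        n=W.shape[0], edges=list(zip(W.row.tolist(), W.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=W.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def transfer_labels(
    ref_embedding: np.ndarray,
    ref_labels,
    query_embedding: np.ndarray,
    k: int = 100,
    min_ref_neighbors: int = 2,
) -> pd.Series:
    """kNN label transfer with abstention.

    Labels each query cell with the modal label of its ``k`` nearest
    reference cells (ties broken by the single nearest reference
    neighbour's label). A query whose ``k`` nearest neighbours in the joint
    reference+query pool contain ``<= min_ref_neighbors`` reference cells is
    labelled ``"NA"``. Use ``k=100`` for class-level and ``k=30`` for
    subclass-level assignment.
    """
    ref_embedding = np.asarray(ref_embedding, dtype=float)
    query_embedding = np.asarray(query_embedding, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if ref_embedding.shape[0] == 0:
        raise DataError("empty reference")
    n_ref = ref_embedding.shape[0]
    k_ref = min(k, n_ref)

    nn_ref = NearestNeighbors(n_neighbors=k_ref).fit(ref_embedding)
    _, ref_idx = nn_ref.kneighbors(query_embedding)

    pool = np.vstack([ref_embedding, query_embedding])
    k_pool = min(k + 1, pool.shape[0])
    nn_pool = NearestNeighbors(n_neighbors=k_pool).fit(pool)
    _, pool_idx = nn_pool.kneighbors(query_embedding)
    # drop the query itself (its index in the pool is n_ref + row)
    own = n_ref + np.arange(query_embedding.shape[0])[:, None]
    n_ref_in_pool = ((pool_idx != own) & (pool_idx < n_ref)).sum(axis=1)

    out = []
    for row, nref in zip(ref_idx, n_ref_in_pool):
        if nref <= min_ref_neighbors:
            out.append("NA")
            continue
        labs, counts = np.unique(ref_labels[row], return_counts=True)
        winners = labs[counts == counts.max()]
        if len(winners) == 1:
            out.append(winners[0])
        else:
            # tie: fall back to the nearest neighbour's label
            nearest = next(l for l in ref_labels[row] if l in winners)
            out.append(nearest)
    return pd.Series(out, name="label")
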