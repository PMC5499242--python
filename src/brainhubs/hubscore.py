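"""Hub location by the importance-contribution / transfer-efficiency index.

The RC index scores each region by combining two ingredients computed on
the weighted graph:

* an importance contribution matrix ``H_BRIM`` whose off-diagonal entry
  ``h_ij = D_i w_ij / (S_bar k_bar^2)`` is region *i*'s degree-and-weight
  scaled contribution to each region it connects to (diagonal 1), where
  ``D_i`` is binary degree, ``S_bar`` mean node strength and ``k_bar``
  mean degree;

* a per-node information-transfer efficiency ``E_i^w`` — a weighted local
  efficiency: the mean inverse shortest weighted distance between ordered
  pairs of distinct neighbors of *i*, normalized by ``D_i (D_i - 1)`` and
  a global ``1/n`` prefactor.  Nodes with fewer than two neighbors get 0.

Shortest weighted distances use edge length ``1/w`` (stronger connection
= shorter distance); the path length is the sum of edge lengths.  The two
ingredients combine into the evaluation matrix ``H_RC`` (row *i* of
``H_BRIM`` scaled by ``E_i^w``, diagonal ``E_i^w``) and the final score

    RC_i = E_i^w * sum_{j != i} D_j w_ji E_j^w / (S_bar k_bar^2).

Regions are ranked by descending RC and the top-k (default 15) flagged as
hubs.  A standard weighted-betweenness ranking on the same 1/w lengths is
provided as the comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .matrices import DimensionError, EmptyNetworkError, WeightedBrainGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeSummary",
    "degree_and_strength",
    "shortest_weighted_distances",
    "information_efficiency",
    "contribution_matrix",
    "evaluation_matrix",
    "rc_scores",
    "select_hubs",
    "weighted_betweenness",
    "strength_scores",
    "random_scores",
    "make_score_table",
]

DEFAULT_N_HUBS = 15


@dataclass(frozen=True)
class DegreeSummary:
    """Per-node binary degree D_i and strength S_i with network means."""

    degree: np.ndarray
    strength: np.ndarray
    mean_degree: float
    mean_strength: float


def degree_and_strength(g: WeightedBrainGraph) -> DegreeSummary:
    """Binary degree, weighted strength, and their means over nodes."""
    a = g.adjacency
    degree = a.sum(axis=1)
    strength = g.weights.sum(axis=1)
    return DegreeSummary(
        degree=degree,
        strength=strength,
        mean_degree=float(degree.mean()),
        mean_strength=float(strength.mean()),
    )


def shortest_weighted_distances(g: WeightedBrainGraph) -> np.ndarray:
    """All-pairs shortest weighted distances with edge length 1/w.

    Returns an ``n x n`` symmetric matrix; disconnected pairs are ``inf``
    and the diagonal is 0.
    """
    w = g.weights
    lengths = np.zeros_like(w)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    return dijkstra(csr_matrix(lengths), directed=False)


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return inv


def information_efficiency(
    g: WeightedBrainGraph, d: np.ndarray | None = None
) -> np.ndarray:
    """Information-transfer efficiency E_i^w of every node.

    For each node *i* with degree >= 2, sum 1/d_jh over ordered pairs
    (j, h) of distinct neighbors of *i* (whole-graph distances), divide by
    ``D_i (D_i - 1)`` and by ``n``.  Disconnected neighbor pairs
    contribute 0; nodes with degree <= 1 score 0.
    """
    if d is None:
        d = shortest_weighted_distances(g)
    n = g.n
    a = g.adjacency.astype(bool)
    degree = a.sum(axis=1)
    inv = _inverse_distances(d)
    e = np.zeros(n)
    for i in range(n):
        if degree[i] < 2:
            continue
        nb = np.flatnonzero(a[i])
        # inv has zero diagonal so the full block sums exactly the j != h pairs
        e[i] = inv[np.ix_(nb, nb)].sum() / (degree[i] * (degree[i] - 1)) / n
    return e


def contribution_matrix(g: WeightedBrainGraph, ds: DegreeSummary | None = None) -> np.ndarray:
    """Importance contribution matrix H_BRIM.

    ``h_ij = D_i w_ij / (S_bar k_bar^2)`` off the diagonal, 1 on it.
    """
    if ds is None:
        ds = degree_and_strength(g)
    if ds.mean_degree <= 0 or ds.mean_strength <= 0:
        raise EmptyNetworkError("contribution matrix undefined on an edgeless network")
    scale = ds.mean_strength * ds.mean_degree**2
    h = (ds.degree[:, None] * g.weights) / scale
    np.fill_diagonal(h, 1.0)
    return h


def evaluation_matrix(h: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Evaluation matrix H_RC: row i of H_BRIM scaled by E_i^w, diagonal E_i^w."""
    if h.shape[0] != h.shape[1] or h.shape[0] != e.shape[0]:
        raise DimensionError("contribution matrix and efficiency vector shapes disagree")
    out = h * e[:, None]
    np.fill_diagonal(out, e)
    return out


def make_score_table(
    g: WeightedBrainGraph, scores: np.ndarray, method: str
) -> pd.DataFrame:
    """Rank raw per-node scores into a hub score table.

    Rank 1 is the highest score; ties are broken by ascending region
    index so the ranking is deterministic.  ``is_hub`` starts all-False;
    use :func:`select_hubs` to flag the top-k.
    """
    n = g.n
    order = np.lexsort((np.arange(n), -np.asarray(scores, dtype=float)))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {
            "region_index": np.arange(n),
            "region_id": list(g.region_ids),
            "score": np.asarray(scores, dtype=float),
            "rank": rank,
            "is_hub": False,
        }
    )
    table.attrs["method"] = method
    return table


def rc_scores(g: WeightedBrainGraph) -> pd.DataFrame:
    """Score every region with the RC importance index.

    Runs the full workflow: degree/strength summary, shortest weighted
    distances, transfer efficiency, and the neighbor-contribution sum.
    """
    if g.n < 2:
        raise DimensionError("need at least 2 regions")
    ds = degree_and_strength(g)
    if ds.mean_degree <= 0:
        raise EmptyNetworkError("RC undefined on an edgeless network")
    d = shortest_weighted_distances(g)
    e = information_efficiency(g, d)
    scale = ds.mean_strength * ds.mean_degree**2
    # sum_j D_j w_ji E_j^w  ==  (D * E) @ W column i; W symmetric, zero diagonal
    contrib = (ds.degree * e) @ g.weights
    rc = e * contrib / scale
    return make_score_table(g, rc, method="rc")


def select_hubs(scores: pd.DataFrame, k: int = DEFAULT_N_HUBS) -> pd.DataFrame:
    """Flag the top ``min(k, n)`` ranked regions as hubs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(scores)
    if k > n:
        logger.warning("requested %d hubs from %d regions; clamping", k, n)
        k = n
    out = scores.copy()
    out["is_hub"] = out["rank"] <= k
    out.attrs["method"] = scores.attrs.get("method", "unknown")
    return out


def _length_graph(g: WeightedBrainGraph) -> nx.Graph:
    gr = nx.Graph()
    gr.add_nodes_from(range(g.n))
    w = g.weights
    for i, j in zip(*np.nonzero(np.triu(w, k=1))):
        gr.add_edge(int(i), int(j), length=1.0 / w[i, j])
    return gr


def weighted_betweenness(g: WeightedBrainGraph) -> pd.DataFrame:
    """Weighted betweenness baseline: unnormalized shortest-path counts.

    Shortest paths use edge length 1/w; endpoints are excluded and each
    unordered pair is counted once, the convention of the Brandes
    algorithm on undirected graphs.
    """
    bc = nx.betweenness_centrality(_length_graph(g), weight="length", normalized=False)
    scores = np.array([bc[i] for i in range(g.n)])
    return make_score_table(g, scores, method="weighted_betweenness")


def strength_scores(g: WeightedBrainGraph) -> pd.DataFrame:
    """Node-strength ranking (simple baseline for recovery comparisons)."""
    return make_score_table(g, g.weights.sum(axis=1), method="strength")


def random_scores(g: WeightedBrainGraph, seed: int) -> pd.DataFrame:
    """Uniformly random ranking from a seeded generator."""
    rng = np.random.default_rng(seed)
    return make_score_table(g, rng.random(g.n), method="random")
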