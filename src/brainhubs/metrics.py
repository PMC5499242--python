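"""Global and per-node network properties.

Density, global efficiency, node strength, the binary clustering
coefficient, and a nodal efficiency (per-node sum of reciprocal shortest
weighted distances).  Node count ``n`` is always the original network
size: the vulnerability analysis zeroes edges without deleting nodes, so
density and efficiency denominators never shrink.

Two different per-node "efficiencies" appear in this package and must not
be conflated: :func:`nodal_efficiency` here (sum of inverse distances
from one node to all others) and the transfer efficiency ``E_i^w`` of
:mod:`brainhubs.hubscore` (a neighborhood quantity used by the RC index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import WeightedBrainGraph
from .hubscore import shortest_weighted_distances

__all__ = [
    "MetricsReport",
    "network_density",
    "global_efficiency",
    "node_strength",
    "mean_strength",
    "clustering",
    "nodal_efficiency",
    "metrics_report",
]


@dataclass(frozen=True)
class MetricsReport:
    """Global and per-node properties of one network."""

    density: float
    global_efficiency: float
    mean_strength: float
    mean_clustering: float
    strength: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    degree: np.ndarray

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "global_efficiency": self.global_efficiency,
            "mean_strength": self.mean_strength,
            "mean_clustering": self.mean_clustering,
        }


def network_density(g: WeightedBrainGraph) -> float:
    """Fraction of possible (ordered) region pairs joined by an edge."""
    n = g.n
    return float(g.adjacency.sum()) / (n * (n - 1))


def _inv(d: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(d)
    ok = np.isfinite(d) & (d > 0)
    inv[ok] = 1.0 / d[ok]
    return inv


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse shortest weighted distance over ordered pairs.

    Infinite (disconnected) distances contribute zero.
    """
    n = d.shape[0]
    return float(_inv(d).sum()) / (n * (n - 1))


def node_strength(g: WeightedBrainGraph) -> np.ndarray:
    """S_i = sum_j w_ij."""
    return g.weights.sum(axis=1)


def mean_strength(g: WeightedBrainGraph) -> float:
    return float(node_strength(g).mean())


def clustering(g: WeightedBrainGraph) -> tuple[np.ndarray, float]:
    """Binary clustering coefficient C_i = 2 t_i / (k_i (k_i - 1)).

    ``t_i`` counts edges among *i*'s neighbors on the binarized graph;
    nodes with degree <= 1 get 0.  Returns (per-node, mean).
    """
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    c = np.zeros(g.n)
    ok = k > 1
    c[ok] = 2.0 * triangles[ok] / (k[ok] * (k[ok] - 1.0))
    return c, float(c.mean())


def nodal_efficiency(g: WeightedBrainGraph, d: np.ndarray | None = None) -> np.ndarray:
    """Per-node local efficiency E_i = sum_{j != i} 1 / d_ij^w."""
    if d is None:
        d = shortest_weighted_distances(g)
    return _inv(d).sum(axis=1)


def metrics_report(g: WeightedBrainGraph) -> MetricsReport:
    """All properties of one network in a single pass."""
    d = shortest_weighted_distances(g)
    c, c_mean = clustering(g)
    s = node_strength(g)
    return MetricsReport(
        density=network_density(g),
        global_efficiency=global_efficiency(d),
        mean_strength=float(s.mean()),
        mean_clustering=c_mean,
        strength=s,
        clustering=c,
        local_efficiency=nodal_efficiency(g, d),
        degree=g.adjacency.sum(axis=1),
    )
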