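from __future__ import annotations

import numpy as np
import pytest

from brainhubs import ConnectivityMatrix, MatrixRole, WeightedBrainGraph


def random_weight_matrix(
    rng: np.random.Generator, n: int, p: float = 0.5, max_w: float = 10.0
) -> np.ndarray:
    """Symmetric nonnegative weights, zero diagonal, edges i.i.d. Bernoulli(p)."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    w = np.where(upper, rng.uniform(0.5, max_w, size=(n, n)), 0.0)
    w = w + w.T
    return w


def random_graph(
    rng: np.random.Generator, n: int, p: float = 0.5, max_w: float = 10.0
) -> WeightedBrainGraph:
    return WeightedBrainGraph.from_array(random_weight_matrix(rng, n, p, max_w))


def graph_from(w) -> WeightedBrainGraph:
    return WeightedBrainGraph.from_array(np.asarray(w, dtype=float))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250921)


@pytest.fixture
def triangle() -> WeightedBrainGraph:
    """Triangle with all weights 2 — the standard hand-checked example."""
    w = np.full((3, 3), 2.0)
    np.fill_diagonal(w, 0.0)
    return graph_from(w)


@pytest.fixture
def star4() -> WeightedBrainGraph:
    """Star: node 0 center, three leaves, unit weights."""
    w = np.zeros((4, 4))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return graph_from(w)


def complete_graph(n: int, weight: float = 1.0) -> WeightedBrainGraph:
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return graph_from(w)


def cycle_graph(n: int, weight: float = 1.0) -> WeightedBrainGraph:
    w = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        w[i, j] = w[j, i] = weight
    return graph_from(w)


def as_matrix(g: WeightedBrainGraph, role: MatrixRole = MatrixRole.NOSFA) -> ConnectivityMatrix:
    return ConnectivityMatrix(g.weights, role, g.region_ids)
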