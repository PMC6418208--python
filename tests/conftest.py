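"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from multidiv import (
    FixtureSpec,
    MultiplexNetwork,
    PairwiseDistanceMatrix,
    er_multiplex,
    reference_four_layer_matrix,
)


@pytest.fixture
def ref_matrix() -> PairwiseDistanceMatrix:
    """The printed 4-element worked example (labels a-d)."""
    return reference_four_layer_matrix()


@pytest.fixture
def three_node_net() -> MultiplexNetwork:
    """Hand-checkable 3-node, 2-layer multiplex used for frozen oracles."""
    return MultiplexNetwork(
        ("a", "b", "c"),
        ("p", "q"),
        {"p": {("a", "b")}, "q": {("a", "b"), ("a", "c")}},
    )


@pytest.fixture
def er_net() -> MultiplexNetwork:
    """Seeded mid-size random multiplex (30 nodes, 3 layers)."""
    return er_multiplex(FixtureSpec(n_nodes=30, n_layers=3,
                                    edge_probability=0.2, seed=42))


def random_distance_matrix(rng: np.random.Generator, k: int,
                           scale: float = 1.0) -> PairwiseDistanceMatrix:
    """Random symmetric matrix with zero diagonal, entries in (0, scale]."""
    vals = rng.uniform(0.01, 1.0, size=(k, k)) * scale
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    labels = tuple(f"e{i:02d}" for i in range(k))
    return PairwiseDistanceMatrix(labels, vals)


def random_ultrametric_matrix(rng: np.random.Generator,
                              k: int) -> PairwiseDistanceMatrix:
    """Random ultrametric distances from a random merge tree with
    strictly increasing heights."""
    clusters = [[i] for i in range(k)]
    vals = np.zeros((k, k))
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.05, 0.3))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                vals[a, b] = vals[b, a] = height
        clusters[i] += clusters.pop(j)
    labels = tuple(f"u{i:02d}" for i in range(k))
    return PairwiseDistanceMatrix(labels, vals)


def diversity_recursive_oracle(dm: PairwiseDistanceMatrix) -> float:
    """Independent top-down memoized evaluation of the diversity recursion.

    Deliberately structured differently from the package's bottom-up bitmask
    dynamic program: plain frozensets of labels and explicit min-distance
    evaluation per call.
    """
    d = {
        (a, b): float(dm.values[i, j])
        for i, a in enumerate(dm.element_labels)
        for j, b in enumerate(dm.element_labels)
    }

    @lru_cache(maxsize=None)
    def u(subset: frozenset) -> float:
        if len(subset) <= 1:
            return 0.0
        best = -np.inf
        for s in subset:
            rest = subset - {s}
            dist = min(d[s, t] for t in rest)
            best = max(best, u(rest) + dist)
        return best

    return u(frozenset(dm.element_labels))


def floyd_warshall_distances(n: int, edge_index_pairs) -> np.ndarray:
    """Brute-force all-pairs shortest paths (unit weights, inf = no path)."""
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i, j in edge_index_pairs:
        dist[i, j] = dist[j, i] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return dist
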