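"""Per-node, per-layer connectivity profiles.

Two probability distributions summarize how a node sits in a layer:

* the **node distance distribution** (NDD): the fraction of the other
  ``N - 1`` nodes at each shortest-path distance, with every unreachable
  node pooled into one dedicated bin;
* the **transition profile**: the one-step random-walk distribution,
  uniform over neighbors, with all mass on an ``INACTIVE`` sentinel when
  the node has no edges in the layer.

Both are exactly the inputs the node-difference measure consumes.  The NDD
excludes the node itself (no zero-distance bin) and normalizes by ``N - 1``
so that an isolated node is a point mass on the unreachable bin while a
node reaching everyone puts all mass on finite bins — which makes the
extreme node-difference value of 1 exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .multiplex_io import MultiplexNetwork

__all__ = [
    "UNREACHABLE",
    "INACTIVE",
    "DistanceProfile",
    "TransitionProfile",
    "node_distance_distribution",
    "transition_profile",
    "layer_ndd_matrix",
    "layer_transition_matrix",
]

#: Label of the pooled bin for nodes with no path from the owner.
UNREACHABLE = "UNREACHABLE"

#: Sentinel outcome of the random walk at a degree-zero node.
INACTIVE = "INACTIVE"


@dataclass(frozen=True)
class DistanceProfile:
    """Shortest-path distance histogram of one node in one layer.

    ``mass`` has ``N`` entries: bins for distances ``1 .. N-1`` followed by
    the unreachable bin.  Entries are non-negative and sum to 1.
    """

    owner_node: str
    layer: str
    mass: np.ndarray

    @property
    def bins(self) -> tuple[object, ...]:
        return tuple(range(1, len(self.mass))) + (UNREACHABLE,)

    @property
    def unreachable_mass(self) -> float:
        return float(self.mass[-1])

    def as_dict(self) -> dict[object, float]:
        return {b: float(m) for b, m in zip(self.bins, self.mass)}


@dataclass(frozen=True)
class TransitionProfile:
    """One-step random-walk distribution of one node in one layer.

    ``mass`` has ``N + 1`` entries aligned with the network's node labels
    followed by the ``INACTIVE`` sentinel.
    """

    owner_node: str
    layer: str
    outcomes: tuple[str, ...]
    mass: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {o: float(m) for o, m in zip(self.outcomes, self.mass)}


def _ndd_mass(graph: nx.Graph, node_order: tuple[str, ...], node: str) -> np.ndarray:
    n = len(node_order)
    mass = np.zeros(n, dtype=float)
    if n == 1:
        mass[-1] = 1.0  # degenerate single-node layer: nothing reachable
        return mass
    lengths = nx.single_source_shortest_path_length(graph, node)
    reachable = 0
    for other, d in lengths.items():
        if other == node:
            continue
        mass[d - 1] += 1.0
        reachable += 1
    mass /= n - 1
    mass[-1] = (n - 1 - reachable) / (n - 1)
    return mass


def node_distance_distribution(
    net: MultiplexNetwork, node: str, layer: str
) -> DistanceProfile:
    """BFS distance histogram of ``node`` within ``layer``.

    Bin ``d`` holds (number of nodes at shortest-path distance ``d``) /
    ``(N - 1)``; nodes without a path contribute to the unreachable bin.
    """
    net.require_node(node)
    net.require_layer(layer)
    graph = net.layer_graph(layer)
    return DistanceProfile(node, layer, _ndd_mass(graph, net.node_labels, node))


def transition_profile(
    net: MultiplexNetwork, node: str, layer: str
) -> TransitionProfile:
    """Uniform-over-neighbors walk step; point mass on INACTIVE if isolated."""
    net.require_node(node)
    net.require_layer(layer)
    outcomes = net.node_labels + (INACTIVE,)
    mass = np.zeros(len(outcomes), dtype=float)
    nbrs = net.neighbors(layer, node)
    if nbrs:
        idx = {lab: i for i, lab in enumerate(net.node_labels)}
        for nb in nbrs:
            mass[idx[nb]] = 1.0 / len(nbrs)
    else:
        mass[-1] = 1.0
    return TransitionProfile(node, layer, outcomes, mass)


def layer_ndd_matrix(net: MultiplexNetwork, layer: str) -> np.ndarray:
    """All NDDs of a layer stacked row-wise (row i = node_labels[i])."""
    net.require_layer(layer)
    graph = net.layer_graph(layer)
    return np.vstack(
        [_ndd_mass(graph, net.node_labels, node) for node in net.node_labels]
    )


def layer_transition_matrix(net: MultiplexNetwork, layer: str) -> np.ndarray:
    """All transition profiles of a layer stacked row-wise, N x (N+1)."""
    net.require_layer(layer)
    n = net.n_nodes
    idx = {lab: i for i, lab in enumerate(net.node_labels)}
    mat = np.zeros((n, n + 1), dtype=float)
    deg = np.zeros(n, dtype=float)
    for u, v in net.edges[layer]:
        i, j = idx[u], idx[v]
        mat[i, j] = 1.0
        mat[j, i] = 1.0
        deg[i] += 1
        deg[j] += 1
    active = deg > 0
    mat[active] /= deg[active, None]
    mat[~active, n] = 1.0
    return mat
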