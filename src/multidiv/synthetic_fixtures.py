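"""Deterministic generators for test multiplexes and reference matrices.

All generators are pure functions of their parameters: the same spec always
yields the same network, bit for bit.  The random generator draws one
Bernoulli variable per unordered node pair, pairs enumerated in label
order, so fixtures are reproducible across implementations given the same
bit generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multiplex_io import MultiplexNetwork, PairwiseDistanceMatrix

__all__ = [
    "FixtureSpec",
    "er_multiplex",
    "reference_four_layer_matrix",
    "perturbation_base_multiplex",
    "perturb_link",
    "REDUNDANT_LINK",
    "NOVEL_LINK",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random multiplex: N nodes, M independent ER layers."""

    n_nodes: int
    n_layers: int
    edge_probability: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_layers < 1:
            raise ValueError("n_nodes and n_layers must be positive")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValueError("edge_probability must lie in [0, 1]")


def _node_labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"n{i:0{width}d}" for i in range(n))


def _layer_labels(m: int) -> tuple[str, ...]:
    width = len(str(m - 1))
    return tuple(f"L{i:0{width}d}" for i in range(m))


def er_multiplex(spec: FixtureSpec) -> MultiplexNetwork:
    """Independent Erdos-Renyi layers on a shared, sorted node set.

    For each layer in order, each pair (i, j) with i < j in label order is
    included with probability ``edge_probability`` using one draw from
    ``numpy.random.default_rng(seed)``.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = _node_labels(spec.n_nodes)
    layers = _layer_labels(spec.n_layers)
    edges: dict[str, frozenset[tuple[str, str]]] = {}
    for layer in layers:
        draws = rng.random(spec.n_nodes * (spec.n_nodes - 1) // 2)
        pairs = (
            (nodes[i], nodes[j])
            for i in range(spec.n_nodes)
            for j in range(i + 1, spec.n_nodes)
        )
        edges[layer] = frozenset(
            pair for pair, x in zip(pairs, draws) if x < spec.edge_probability
        )
    return MultiplexNetwork(nodes, layers, edges)


def reference_four_layer_matrix() -> PairwiseDistanceMatrix:
    """The worked 4-element example: labels a-d with known pairwise values.

    Off-diagonals: d(a,b)=0.697, d(a,c)=0.214, d(a,d)=0.786, d(b,c)=0.580,
    d(b,d)=0.692, d(c,d)=0.804.  Its diversity is 1.692 with elimination
    order c, b and final pair {a, d}.
    """
    labels = ("a", "b", "c", "d")
    vals = np.array(
        [
            [0.0, 0.697, 0.214, 0.786],
            [0.697, 0.0, 0.580, 0.692],
            [0.214, 0.580, 0.0, 0.804],
            [0.786, 0.692, 0.804, 0.0],
        ]
    )
    return PairwiseDistanceMatrix(labels, vals)


#: Canonical perturbations of :func:`perturbation_base_multiplex`:
#: (layer, u, v) for the redundant and the novel link addition.
REDUNDANT_LINK = ("b", "3", "4")
NOVEL_LINK = ("b", "1", "2")


def perturbation_base_multiplex() -> MultiplexNetwork:
    """A 6-node, 4-layer multiplex built for link-perturbation experiments.

    Structure chosen so that:

    * edge 3-4 (:data:`REDUNDANT_LINK`) is present in layers a, c and d but
      absent from b, where nodes 3 and 4 are already connected to the rest —
      adding it to b contributes only redundant information and lowers
      global diversity;
    * edge 1-2 (:data:`NOVEL_LINK`) is absent from every layer and node 2
      is peripheral (a leaf) in b — adding it to b creates genuinely new
      connectivity and raises global diversity.
    """
    nodes = tuple("123456")
    edges = {
        "a": frozenset(
            {("1", "4"), ("1", "6"), ("3", "4"), ("4", "5"), ("5", "6")}
        ),
        "b": frozenset(
            {("1", "3"), ("1", "5"), ("1", "6"), ("2", "4"), ("4", "5"),
             ("4", "6")}
        ),
        "c": frozenset(
            {("1", "3"), ("2", "4"), ("3", "4"), ("4", "6")}
        ),
        "d": frozenset(
            {("1", "5"), ("2", "5"), ("3", "4"), ("3", "5")}
        ),
    }
    return MultiplexNetwork(nodes, ("a", "b", "c", "d"), edges)


def perturb_link(
    net: MultiplexNetwork, layer: str, u: str, v: str, mode: str
) -> MultiplexNetwork:
    """Copy of ``net`` with one edge added to or removed from one layer.

    Raises on no-ops: adding an existing edge or removing an absent one.
    """
    net.require_layer(layer)
    net.require_node(u)
    net.require_node(v)
    if u == v:
        raise ValueError("cannot perturb a self-loop")
    edge = (u, v) if u <= v else (v, u)
    present = edge in net.edges[layer]
    if mode == "add":
        if present:
            raise ValueError(f"edge {edge} already present in layer {layer!r}")
        new_edges = net.edges[layer] | {edge}
    elif mode == "remove":
        if not present:
            raise ValueError(f"edge {edge} absent from layer {layer!r}")
        new_edges = net.edges[layer] - {edge}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    edges = dict(net.edges)
    edges[layer] = frozenset(new_edges)
    return MultiplexNetwork(net.node_labels, net.layer_labels, edges)
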