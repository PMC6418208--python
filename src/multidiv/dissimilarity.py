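"""Information-theoretic distances between a node's (or a layer's) profiles.

The node difference between two layers combines the Jensen-Shannon
divergence of the node's distance distributions with that of its one-step
walk profiles:

    value = (sqrt(J_ndd) + sqrt(J_walk)) / (2 * sqrt(ln 2))

Entropies are in nats, so each JS term lies in [0, ln 2] and the value in
[0, 1]: 0 for identical connectivity, 1 when the node is isolated in one
layer and reaches every node in the other.  The layer difference is the
plain mean of node differences over the shared node set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .layer_statistics import (
    layer_ndd_matrix,
    layer_transition_matrix,
    node_distance_distribution,
    transition_profile,
)
from .multiplex_io import MultiplexNetwork, PairwiseDistanceMatrix

__all__ = [
    "LN2",
    "NodeDifferenceResult",
    "shannon_entropy",
    "js_divergence",
    "node_difference",
    "layer_difference",
    "layer_distance_matrix",
    "node_distance_matrix",
]

LN2 = float(np.log(2.0))
_NORMALIZER = 2.0 * float(np.sqrt(np.log(2.0)))


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D distribution")
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative mass")
    total = float(arr.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {total!r}, not 1")
    return arr


def shannon_entropy(p) -> float:
    """Entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    arr = _check_distribution(p, "p")
    return float(-xlogy(arr, arr).sum())


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence H((p+q)/2) - (H(p)+H(q))/2, in nats.

    Both distributions must be aligned on a common outcome set (same
    length, same meaning per coordinate).  The result lies in [0, ln 2];
    it is 0 iff p == q and ln 2 iff the supports are disjoint.
    """
    ap = _check_distribution(p, "p")
    aq = _check_distribution(q, "q")
    if ap.shape != aq.shape:
        raise ValueError(
            f"outcome sets differ: {ap.shape[0]} vs {aq.shape[0]} outcomes"
        )
    m = (ap + aq) / 2.0
    val = float(-xlogy(m, m).sum() + (xlogy(ap, ap).sum() + xlogy(aq, aq).sum()) / 2.0)
    return min(max(val, 0.0), LN2)


def _js_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise JS divergence of two stacked distribution matrices."""
    m = (a + b) / 2.0
    val = -xlogy(m, m).sum(axis=1) + (
        xlogy(a, a).sum(axis=1) + xlogy(b, b).sum(axis=1)
    ) / 2.0
    return np.clip(val, 0.0, LN2)


@dataclass(frozen=True)
class NodeDifferenceResult:
    """Node difference between two layers, with its two JS components."""

    node: str
    layer_pair: tuple[str, str]
    ndd_term: float
    transition_term: float

    @property
    def value(self) -> float:
        return (np.sqrt(self.ndd_term) + np.sqrt(self.transition_term)) / _NORMALIZER


def node_difference(
    net: MultiplexNetwork, node: str, layer_p: str, layer_q: str
) -> NodeDifferenceResult:
    """Distance in [0, 1] between a node's connectivity in two layers."""
    ndd_p = node_distance_distribution(net, node, layer_p)
    ndd_q = node_distance_distribution(net, node, layer_q)
    t_p = transition_profile(net, node, layer_p)
    t_q = transition_profile(net, node, layer_q)
    return NodeDifferenceResult(
        node=node,
        layer_pair=(layer_p, layer_q),
        ndd_term=js_divergence(ndd_p.mass, ndd_q.mass),
        transition_term=js_divergence(t_p.mass, t_q.mass),
    )


def _all_node_differences(
    net: MultiplexNetwork, layer_p: str, layer_q: str
) -> np.ndarray:
    """Vector of node-difference values, one per node in label order."""
    ndd = _js_rows(layer_ndd_matrix(net, layer_p), layer_ndd_matrix(net, layer_q))
    trans = _js_rows(
        layer_transition_matrix(net, layer_p), layer_transition_matrix(net, layer_q)
    )
    return (np.sqrt(ndd) + np.sqrt(trans)) / _NORMALIZER


def layer_difference(net: MultiplexNetwork, layer_p: str, layer_q: str) -> float:
    """Mean node difference over all N nodes (inactive nodes included)."""
    return float(_all_node_differences(net, layer_p, layer_q).mean())


def layer_distance_matrix(net: MultiplexNetwork) -> PairwiseDistanceMatrix:
    """Symmetric M x M matrix of layer differences."""
    layers = net.layer_labels
    m = len(layers)
    vals = np.zeros((m, m), dtype=float)
    ndd = {l: layer_ndd_matrix(net, l) for l in layers}
    trans = {l: layer_transition_matrix(net, l) for l in layers}
    for i in range(m):
        for j in range(i + 1, m):
            per_node = (
                np.sqrt(_js_rows(ndd[layers[i]], ndd[layers[j]]))
                + np.sqrt(_js_rows(trans[layers[i]], trans[layers[j]]))
            ) / _NORMALIZER
            vals[i, j] = vals[j, i] = float(per_node.mean())
    return PairwiseDistanceMatrix(layers, vals)


def node_distance_matrix(net: MultiplexNetwork, node: str) -> PairwiseDistanceMatrix:
    """Symmetric M x M matrix of one node's differences across layer pairs."""
    net.require_node(node)
    layers = net.layer_labels
    m = len(layers)
    vals = np.zeros((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            res = node_difference(net, node, layers[i], layers[j])
            vals[i, j] = vals[j, i] = float(res.value)
    return PairwiseDistanceMatrix(layers, vals)
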