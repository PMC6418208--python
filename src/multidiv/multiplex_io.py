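"""Reading, validating and writing multiplex networks and distance matrices.

The on-disk formats are plain text:

* **Single-file extended edge list** — one record per intra-layer edge,
  ``layer u v [w]``, whitespace- or comma-separated.  ``#``-comments are
  allowed; a ``#LAYER <label>`` declaration registers a layer even when it
  carries no edges, and a ``#NODES <labels...>`` declaration registers
  nodes, so edge-free layers and isolated nodes survive round-trips.
* **Per-layer directory** — one two-column ``<layer>.edges`` file per layer.
* **Distance matrix** — CSV with the element labels in the header row and
  in the first column, and a square numeric body.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexNetwork",
    "PairwiseDistanceMatrix",
    "MultiplexFormatError",
    "read_multiplex_edgelist",
    "write_multiplex_edgelist",
    "read_distance_matrix",
    "write_distance_matrix",
]


class MultiplexFormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class MultiplexNetwork:
    """A set of simple undirected layers sharing one labeled node set.

    ``node_labels`` and ``layer_labels`` are stored sorted so that equality
    and serialization are independent of construction order.  Nodes carrying
    no edge in a layer are *inactive* there: present but isolated.
    """

    node_labels: tuple[str, ...]
    layer_labels: tuple[str, ...]
    edges: Mapping[str, frozenset[tuple[str, str]]]

    def __post_init__(self) -> None:
        nodes = tuple(sorted(dict.fromkeys(self.node_labels)))
        layers = tuple(sorted(dict.fromkeys(self.layer_labels)))
        if len(nodes) != len(self.node_labels):
            raise MultiplexFormatError("duplicate node labels")
        if len(layers) != len(self.layer_labels):
            raise MultiplexFormatError("duplicate layer labels")
        if not nodes:
            raise MultiplexFormatError("a multiplex needs at least one node")
        if not layers:
            raise MultiplexFormatError("a multiplex needs at least one layer")
        object.__setattr__(self, "node_labels", nodes)
        object.__setattr__(self, "layer_labels", layers)
        node_set = set(nodes)
        canon: dict[str, frozenset[tuple[str, str]]] = {}
        for layer in layers:
            layer_edges = set()
            for u, v in self.edges.get(layer, ()):  # type: ignore[union-attr]
                if u == v:
                    raise MultiplexFormatError(
                        f"self-loop {u!r}-{v!r} in layer {layer!r}"
                    )
                if u not in node_set or v not in node_set:
                    raise MultiplexFormatError(
                        f"edge ({u!r}, {v!r}) in layer {layer!r} uses unknown nodes"
                    )
                layer_edges.add(_canonical_edge(u, v))
            canon[layer] = frozenset(layer_edges)
        extra = set(self.edges) - set(layers)
        if extra:
            raise MultiplexFormatError(f"edges for undeclared layers: {sorted(extra)}")
        object.__setattr__(self, "edges", canon)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_layers(self) -> int:
        return len(self.layer_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiplexNetwork):
            return NotImplemented
        return (
            self.node_labels == other.node_labels
            and self.layer_labels == other.layer_labels
            and dict(self.edges) == dict(other.edges)
        )

    def __hash__(self) -> int:
        return hash(
            (self.node_labels, self.layer_labels,
             tuple(sorted((k, v) for k, v in self.edges.items())))
        )

    def require_node(self, node: str) -> None:
        if node not in set(self.node_labels):
            raise KeyError(f"unknown node {node!r}")

    def require_layer(self, layer: str) -> None:
        if layer not in self.edges:
            raise KeyError(f"unknown layer {layer!r}")

    def layer_graph(self, layer: str) -> nx.Graph:
        """The layer as a :class:`networkx.Graph` over the full node set."""
        self.require_layer(layer)
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges[layer])
        return g

    def neighbors(self, layer: str, node: str) -> tuple[str, ...]:
        self.require_layer(layer)
        self.require_node(node)
        out = []
        for u, v in self.edges[layer]:
            if u == node:
                out.append(v)
            elif v == node:
                out.append(u)
        return tuple(sorted(out))


@dataclass(frozen=True)
class PairwiseDistanceMatrix:
    """Symmetric non-negative distances between labeled elements.

    The diagonal must be exactly zero and the matrix symmetric within 1e-12.
    Entries produced by the layer/node difference measures lie in [0, 1];
    the type itself only requires non-negativity so that rescaled matrices
    remain representable.
    """

    element_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.element_labels)
        if len(set(labels)) != len(labels):
            raise MultiplexFormatError("duplicate element labels")
        if not labels:
            raise MultiplexFormatError("at least one element required")
        vals = np.asarray(self.values, dtype=float)
        k = len(labels)
        if vals.shape != (k, k):
            raise MultiplexFormatError(
                f"matrix shape {vals.shape} does not match {k} labels"
            )
        if not np.all(np.isfinite(vals)):
            raise MultiplexFormatError("non-finite entries")
        if np.any(vals < 0):
            raise MultiplexFormatError("negative distance entries")
        if np.any(np.diag(vals) != 0):
            raise MultiplexFormatError("diagonal must be exactly zero")
        if np.max(np.abs(vals - vals.T), initial=0.0) > 1e-12:
            raise MultiplexFormatError("matrix is not symmetric")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        vals.flags.writeable = False
        object.__setattr__(self, "element_labels", labels)
        object.__setattr__(self, "values", vals)

    @property
    def size(self) -> int:
        return len(self.element_labels)

    def index(self, label: str) -> int:
        try:
            return self.element_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown element {label!r}") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.index(p) for p in pair)
        return float(self.values[i, j])

    def submatrix(self, labels: Iterable[str]) -> "PairwiseDistanceMatrix":
        keep = tuple(labels)
        idx = [self.index(l) for l in keep]
        return PairwiseDistanceMatrix(keep, self.values[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairwiseDistanceMatrix):
            return NotImplemented
        return self.element_labels == other.element_labels and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((self.element_labels, self.values.tobytes()))


# -- edge-list I/O -------------------------------------------------------------


def _split_record(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",") if tok.strip()]
    return line.split()


def read_multiplex_edgelist(
    path: str | os.PathLike, dialect: str = "single-file"
) -> MultiplexNetwork:
    """Parse a multiplex edge list into a validated :class:`MultiplexNetwork`.

    ``dialect`` is ``"single-file"`` (records ``layer u v [w]``) or
    ``"per-layer-directory"`` (``<layer>.edges`` files with two columns).
    Weights are ignored, self-loops and duplicate edges dropped, each with a
    logged warning.  The node set is the union over all layers.
    """
    p = Path(path)
    if dialect == "single-file":
        layers, edges, seen = _parse_single_file(p)
    elif dialect == "per-layer-directory":
        layers, edges, seen = _parse_directory(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    nodes = sorted(seen)
    if not nodes:
        # edge-free network: every declared layer is empty, nodes unknown
        raise MultiplexFormatError(f"{p}: no nodes found in input")
    return MultiplexNetwork(tuple(nodes), tuple(layers), {
        layer: frozenset(es) for layer, es in edges.items()
    })


def _parse_single_file(
    p: Path,
) -> tuple[list[str], dict[str, set[tuple[str, str]]], set[str]]:
    if not p.is_file():
        raise MultiplexFormatError(f"no such file: {p}")
    layers: list[str] = []
    edges: dict[str, set[tuple[str, str]]] = {}
    seen: set[str] = set()
    warned_weight = False
    n_records = 0
    with open(p) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.upper().startswith("NODES"):
                    seen.update(body[5:].split())
                elif body.upper().startswith("LAYER"):
                    label = body[5:].strip()
                    if not label:
                        raise MultiplexFormatError(
                            f"{p}:{lineno}: #LAYER declaration without a label"
                        )
                    if label not in edges:
                        layers.append(label)
                        edges[label] = set()
                continue
            toks = _split_record(line)
            if len(toks) not in (3, 4):
                raise MultiplexFormatError(
                    f"{p}:{lineno}: expected 'layer u v [w]', got {line!r}"
                )
            if len(toks) == 4 and not warned_weight:
                logger.warning("%s:%d: weight column ignored", p, lineno)
                warned_weight = True
            layer, u, v = toks[0], toks[1], toks[2]
            if layer not in edges:
                layers.append(layer)
                edges[layer] = set()
            n_records += 1
            seen.update((u, v))
            _add_edge(edges[layer], layer, u, v, where=f"{p}:{lineno}")
    if n_records == 0 and not layers:
        raise MultiplexFormatError(f"{p}: empty file")
    return layers, edges, seen


def _parse_directory(
    p: Path,
) -> tuple[list[str], dict[str, set[tuple[str, str]]], set[str]]:
    if not p.is_dir():
        raise MultiplexFormatError(f"no such directory: {p}")
    files = sorted(p.glob("*.edges"))
    if not files:
        raise MultiplexFormatError(f"{p}: no *.edges files found")
    layers: list[str] = []
    edges: dict[str, set[tuple[str, str]]] = {}
    seen: set[str] = set()
    for f in files:
        label = f.stem.strip()
        if label in edges:
            raise MultiplexFormatError(f"duplicate layer label {label!r} in {p}")
        layers.append(label)
        edges[label] = set()
        with open(f) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                toks = _split_record(line)
                if len(toks) not in (2, 3):
                    raise MultiplexFormatError(
                        f"{f}:{lineno}: expected 'u v [w]', got {line!r}"
                    )
                seen.update((toks[0], toks[1]))
                _add_edge(edges[label], label, toks[0], toks[1],
                          where=f"{f}:{lineno}")
    return layers, edges, seen


def _add_edge(
    bucket: set[tuple[str, str]], layer: str, u: str, v: str, where: str
) -> None:
    if u == v:
        logger.warning("%s: dropping self-loop %s-%s in layer %s", where, u, v, layer)
        return
    edge = _canonical_edge(u, v)
    if edge in bucket:
        logger.warning("%s: dropping duplicate edge %s-%s in layer %s",
                       where, u, v, layer)
        return
    bucket.add(edge)


def write_multiplex_edgelist(net: MultiplexNetwork, path: str | os.PathLike) -> None:
    """Write ``net`` in the single-file dialect; ``read(write(net)) == net``.

    Layers appear in label order, each introduced by a ``#LAYER`` declaration
    (so edge-free layers are preserved), edges sorted within a layer.  A
    ``#NODES`` header carries the full node set so isolated nodes survive.
    """
    lines = ["#NODES " + " ".join(net.node_labels)]
    for layer in net.layer_labels:
        lines.append(f"#LAYER {layer}")
        for u, v in sorted(net.edges[layer]):
            lines.append(f"{layer} {u} {v}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- distance-matrix I/O -------------------------------------------------------


def read_distance_matrix(path: str | os.PathLike) -> PairwiseDistanceMatrix:
    """Read a labeled square distance matrix from CSV.

    Asymmetries up to 1e-9 are symmetrized; anything larger is an error, as
    are negative entries, entries above 1, non-square bodies and mismatched
    row/column labels.
    """
    p = Path(path)
    if not p.is_file():
        raise MultiplexFormatError(f"no such file: {p}")
    try:
        df = pd.read_csv(p, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MultiplexFormatError(f"{p}: cannot parse CSV ({exc})") from exc
    if df.shape[0] != df.shape[1]:
        raise MultiplexFormatError(f"{p}: matrix body is not square {df.shape}")
    cols = [str(c).strip() for c in df.columns]
    rows = [str(r).strip() for r in df.index]
    if cols != rows:
        raise MultiplexFormatError(f"{p}: row labels do not match column labels")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MultiplexFormatError(f"{p}: non-numeric entries ({exc})") from exc
    if np.any(vals < 0):
        raise MultiplexFormatError(f"{p}: negative distance entries")
    if np.any(vals > 1):
        raise MultiplexFormatError(f"{p}: entries above 1")
    asym = float(np.max(np.abs(vals - vals.T), initial=0.0))
    if asym > 1e-9:
        raise MultiplexFormatError(f"{p}: asymmetry {asym:.3g} exceeds 1e-9")
    vals = (vals + vals.T) / 2.0
    if np.any(np.abs(np.diag(vals)) > 1e-9):
        raise MultiplexFormatError(f"{p}: nonzero diagonal")
    np.fill_diagonal(vals, 0.0)
    return PairwiseDistanceMatrix(tuple(cols), vals)


def write_distance_matrix(
    dm: PairwiseDistanceMatrix, path: str | os.PathLike
) -> None:
    """Write a distance matrix as labeled CSV (full float precision)."""
    df = pd.DataFrame(dm.values, index=dm.element_labels, columns=dm.element_labels)
    df.to_csv(path, float_format="%.17g")
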