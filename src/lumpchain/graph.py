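"""Graph data model, file I/O, connectivity and node statistics.

A :class:`Network` stores a dense nonnegative weight matrix ``W`` where
``W[i, j]`` is the weight of the edge ``i -> j``.  Undirected networks are
stored symmetrically: an undirected edge ``{i, j}`` contributes its weight
to both ``(i, j)`` and ``(j, i)``, so the total weight counts every
undirected edge twice.  All random-walk formulas downstream are written
against this convention, which makes the stationary distribution of the
walker on an undirected network equal to the normalized node strengths.

Node indexing is 0-based and dense internally; files use string labels.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParseError, ValidationError

__all__ = [
    "Network",
    "NodeStats",
    "read_network",
    "write_network",
    "strongly_connected_components",
    "restrict_to_component",
    "node_stats",
]

FORMATS = ("edgelist", "gml", "pajek")


@dataclasses.dataclass(frozen=True)
class Network:
    """A node-labelled weighted graph.

    Parameters
    ----------
    node_labels
        Unique string labels, one per node, in internal index order.
    weights
        N x N matrix of nonnegative edge weights (``weights[i, j]`` is the
        weight of ``i -> j``).  Exactly symmetric when ``directed`` is False.
    directed
        Whether edge orientation is meaningful.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    directed: bool

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))
        n = len(self.node_labels)
        if W.shape != (n, n):
            raise ValidationError(
                f"weight matrix shape {W.shape} does not match {n} node labels"
            )
        if len(set(self.node_labels)) != n:
            raise ValidationError("duplicate node labels")
        if not np.all(np.isfinite(W)):
            raise ValidationError("weights contain NaN or inf")
        if np.any(W < 0):
            raise ValidationError("negative edge weights are not allowed")
        if not self.directed and not np.array_equal(W, W.T):
            raise ValidationError(
                "undirected network requires an exactly symmetric weight matrix"
            )

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def edge_count(self) -> int:
        """Number of nonzero ordered pairs (directed) or unordered pairs."""
        nz = self.weights != 0
        if self.directed:
            return int(np.count_nonzero(nz))
        return int(np.count_nonzero(np.triu(nz)))

    def index(self, label: str) -> int:
        try:
            return self.node_labels.index(str(label))
        except ValueError:
            raise ValidationError(f"unknown node label: {label!r}") from None

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.node_labels)}
        try:
            return np.array([lut[str(x)] for x in labels], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown node label: {e.args[0]!r}") from None

    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        G = nx.DiGraph() if self.directed else nx.Graph()
        G.add_nodes_from(self.node_labels)
        idx = np.argwhere(self.weights != 0)
        for i, j in idx:
            if not self.directed and i > j:
                continue
            G.add_edge(self.node_labels[i], self.node_labels[j],
                       weight=float(self.weights[i, j]))
        return G


@dataclasses.dataclass(frozen=True)
class NodeStats:
    """Per-node degrees and strengths plus network-level aggregates."""

    degree: np.ndarray
    in_strength: np.ndarray
    out_strength: np.ndarray
    total_strength: np.ndarray
    average_degree: float
    total_weight: float


def _finish(labels: list[str], W: np.ndarray, directed: bool) -> Network:
    if W.size and W.sum() == 0:
        # zero-weight rows were dropped; an all-zero matrix is still valid
        pass
    return Network(tuple(labels), W, directed)


def read_network(path, format: str = "edgelist", directed: bool = False) -> Network:
    """Read a network from ``path`` in the named dialect.

    Edge-list rows are ``src dst [weight]`` (whitespace separated, ``#``
    comments); the weight defaults to 1 and duplicate edges sum their
    weights.  Node labels appear in first-appearance order.  GML and Pajek
    files are read through networkx.
    """
    if format not in FORMATS:
        raise ValidationError(f"unsupported format {format!r}; choose from {FORMATS}")
    if format == "edgelist":
        return _read_edgelist(path, directed)
    if format == "gml":
        G = nx.read_gml(path, label="label")
    else:
        G = nx.read_pajek(path)
    return _from_networkx(G, directed)


def _read_edgelist(path, directed: bool) -> Network:
    labels: list[str] = []
    lut: dict[str, int] = {}
    rows: list[tuple[int, int, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped.startswith("# nodes:"):
                # optional node-order directive written by write_network
                for lab in stripped[len("# nodes:"):].split():
                    if lab not in lut:
                        lut[lab] = len(labels)
                        labels.append(lab)
                continue
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}: line {lineno}: expected 'src dst [weight]'")
            src, dst = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: weight {parts[2]!r} is not a number"
                    ) from None
            else:
                w = 1.0
            if not np.isfinite(w):
                raise ParseError(f"{path}: line {lineno}: non-finite weight")
            if w < 0:
                raise ValidationError(f"{path}: line {lineno}: negative weight {w}")
            if w == 0:
                continue  # zero-weight rows are dropped
            for lab in (src, dst):
                if lab not in lut:
                    lut[lab] = len(labels)
                    labels.append(lab)
            rows.append((lut[src], lut[dst], w))
    n = len(labels)
    W = np.zeros((n, n))
    for i, j, w in rows:
        W[i, j] += w
        if not directed and i != j:
            W[j, i] += w
    return _finish(labels, W, directed)


def _from_networkx(G, directed: bool) -> Network:
    labels = [str(v) for v in G.nodes()]
    lut = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    g_directed = G.is_directed()
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValidationError(f"negative weight on edge ({u}, {v})")
        if w == 0:
            continue
        i, j = lut[str(u)], lut[str(v)]
        W[i, j] += w
        if not g_directed and i != j:
            W[j, i] += w
    if g_directed and not directed:
        if not np.array_equal(W, W.T):
            raise ValidationError(
                "directed file has asymmetric weights; cannot load as undirected"
            )
    return _finish(labels, W, directed)


def write_network(net: Network, path, format: str = "edgelist") -> None:
    """Write ``net`` so that :func:`read_network` round-trips it exactly.

    Only the edge-list dialect is writable; GML/Pajek support is read-only.
    Weights are printed with 17 significant digits so the round trip is
    exact in IEEE double precision.
    """
    if format != "edgelist":
        raise ValidationError(f"writing format {format!r} is not supported")
    if net.edge_count == 0:
        raise ValidationError("network has no edges to serialize")
    if any(len(lab.split()) != 1 for lab in net.node_labels):
        raise ValidationError("edge-list labels cannot contain whitespace")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {'directed' if net.directed else 'undirected'} edge list\n")
        fh.write("# nodes: " + " ".join(net.node_labels) + "\n")
        nz = np.argwhere(net.weights != 0)
        for i, j in nz:
            if not net.directed and i > j:
                continue
            fh.write(
                f"{net.node_labels[i]}\t{net.node_labels[j]}\t"
                f"{net.weights[i, j]:.17g}\n"
            )


def strongly_connected_components(net: Network) -> list[set[str]]:
    """Strongly connected components (connected components if undirected).

    Returned as label sets ordered by the smallest internal node index
    they contain; their union is the whole node set.
    """
    A = csr_matrix(net.weights != 0)
    _, member = connected_components(
        A, directed=net.directed, connection="strong" if net.directed else "weak"
    )
    comps: dict[int, set[str]] = {}
    order: list[int] = []
    for i, c in enumerate(member):
        if c not in comps:
            comps[c] = set()
            order.append(c)
        comps[c].add(net.node_labels[i])
    return [comps[c] for c in order]


def restrict_to_component(net: Network, component: Iterable[str]) -> Network:
    """Induced subgraph on one strongly connected component.

    ``component`` must be exactly one of the components returned by
    :func:`strongly_connected_components`; original labels are preserved.
    """
    comp = set(str(x) for x in component)
    sccs = strongly_connected_components(net)
    if comp not in sccs:
        raise ValidationError(
            "component is not a strongly connected component of the network"
        )
    keep = [i for i, lab in enumerate(net.node_labels) if lab in comp]
    idx = np.array(keep, dtype=int)
    return Network(
        tuple(net.node_labels[i] for i in keep),
        net.weights[np.ix_(idx, idx)],
        net.directed,
    )


def largest_scc(net: Network) -> Network:
    """Restrict to the largest strongly connected component."""
    comps = strongly_connected_components(net)
    biggest = max(comps, key=len)
    return restrict_to_component(net, biggest)


def node_stats(net: Network) -> NodeStats:
    """Degrees, strengths and total weight.

    For directed networks the degree is the total (in + out) degree and the
    total strength is in-strength + out-strength; for undirected networks
    in- and out-strength coincide with the row sums of the symmetric weight
    matrix (a self-loop counts twice in the degree, once in the strength).
    """
    W = net.weights
    A = (W != 0).astype(int)
    in_s = W.sum(axis=0)
    out_s = W.sum(axis=1)
    if net.directed:
        degree = A.sum(axis=0) + A.sum(axis=1)
        total_s = in_s + out_s
    else:
        degree = A.sum(axis=1) + np.diag(A)
        total_s = out_s
    return NodeStats(
        degree=degree,
        in_strength=in_s,
        out_strength=out_s,
        total_strength=total_s,
        average_degree=float(degree.mean()) if net.N else 0.0,
        total_weight=float(W.sum()),
    )
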