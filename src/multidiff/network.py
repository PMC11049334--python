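"""Multiscale interactome model and the biased random-walk transition matrix.

The network mixes two node kinds — proteins and biological functions — and
three typed edge classes:

* ``ppi``        protein–protein interaction, undirected
* ``annotation`` protein–function annotation, undirected
* ``hierarchy``  function–function relation, stored child→parent; the walk
  may traverse it upward (child→parent) or downward (parent→child), and the
  two directions can carry distinct class weights.

Every typed edge is expanded into directed *moves*, each move weighted by a
per-class scalar; a node's outgoing moves are normalized to a probability
row, producing a row-stochastic biased transition matrix. Nodes with no
outgoing moves form the dangling set ``J`` handled by the diffusion solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

NODE_KINDS = ("protein", "function")
EDGE_KINDS = ("ppi", "annotation", "hierarchy")


class NetworkValidationError(ValueError):
    """Raised when node/edge records violate the multiscale-network contract."""


@dataclass(frozen=True)
class Node:
    """A network node: a protein or a biological function."""

    id: str
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkValidationError(
                f"node {self.id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class TypedEdge:
    """A typed edge; ``hierarchy`` edges are directed child→parent."""

    source: str
    target: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise NetworkValidationError(
                f"edge {self.source!r}->{self.target!r}: kind must be one of "
                f"{EDGE_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class EdgeWeightScheme:
    """Scalar walk-bias weight per transition class.

    All weights default to 1.0 (an unbiased walk on the untyped union graph).
    The walk can be biased, e.g. toward biological functions, by raising
    ``protein_to_function`` relative to ``ppi``; no particular bias values
    are baked in.
    """

    ppi: float = 1.0
    protein_to_function: float = 1.0
    function_to_protein: float = 1.0
    hierarchy_up: float = 1.0
    hierarchy_down: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"weight {name} must be finite and > 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "ppi": self.ppi,
            "protein_to_function": self.protein_to_function,
            "function_to_protein": self.function_to_protein,
            "hierarchy_up": self.hierarchy_up,
            "hierarchy_down": self.hierarchy_down,
        }


@dataclass
class MultiscaleNetwork:
    """Validated multiscale network with a stable, lexicographic node index."""

    nodes: dict[str, Node]
    edges: list[TypedEdge]
    ids: list[str] = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.ids = sorted(self.nodes)
        self.index = {nid: i for i, nid in enumerate(self.ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def kinds(self) -> np.ndarray:
        """Node kinds aligned with the node index."""
        return np.array([self.nodes[nid].kind for nid in self.ids])

    def protein_ids(self) -> list[str]:
        return [nid for nid in self.ids if self.nodes[nid].kind == "protein"]

    def function_ids(self) -> list[str]:
        return [nid for nid in self.ids if self.nodes[nid].kind == "function"]

    def graph(self) -> nx.Graph:
        """Undirected untyped union graph; node attr ``kind``, edge attr ``kind``."""
        g = nx.Graph()
        for nid in self.ids:
            g.add_node(nid, kind=self.nodes[nid].kind)
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind)
        return g

    def ppi_graph(self) -> nx.Graph:
        """The protein–protein layer only."""
        g = nx.Graph()
        g.add_nodes_from(self.protein_ids())
        g.add_edges_from(
            (e.source, e.target) for e in self.edges if e.kind == "ppi"
        )
        return g


def _canonical(edge: TypedEdge, nodes: Mapping[str, Node]) -> TypedEdge:
    """Canonicalize storage: ppi endpoints sorted, annotation protein-first."""
    if edge.kind == "ppi":
        s, t = sorted((edge.source, edge.target))
        return TypedEdge(s, t, "ppi")
    if edge.kind == "annotation":
        if nodes[edge.source].kind == "protein":
            return edge
        return TypedEdge(edge.target, edge.source, "annotation")
    return edge  # hierarchy keeps its child→parent direction


def build_network(
    node_records: Iterable[Node | Mapping[str, str]],
    edge_records: Iterable[TypedEdge | Mapping[str, str]],
) -> MultiscaleNetwork:
    """Validate records and assemble a :class:`MultiscaleNetwork`.

    Records may be :class:`Node`/:class:`TypedEdge` instances or mappings
    with the corresponding keys. Duplicate edges are dropped with a warning;
    self-loops, unknown endpoints, kind/endpoint mismatches and hierarchy
    cycles raise :class:`NetworkValidationError`.
    """
    nodes: dict[str, Node] = {}
    for rec in node_records:
        node = rec if isinstance(rec, Node) else Node(
            id=str(rec["id"]), kind=str(rec["kind"]), label=str(rec.get("label", ""))
        )
        if node.id in nodes:
            raise NetworkValidationError(f"duplicate node id {node.id!r}")
        nodes[node.id] = node
    if not nodes:
        raise NetworkValidationError("network has no nodes")

    seen: set[tuple[str, str, str]] = set()
    edges: list[TypedEdge] = []
    n_dup = 0
    for rec in edge_records:
        edge = rec if isinstance(rec, TypedEdge) else TypedEdge(
            source=str(rec["source"]), target=str(rec["target"]), kind=str(rec["kind"])
        )
        for endpoint in (edge.source, edge.target):
            if endpoint not in nodes:
                raise NetworkValidationError(
                    f"edge {edge.source!r}->{edge.target!r} ({edge.kind}): "
                    f"unknown endpoint id {endpoint!r}"
                )
        if edge.source == edge.target:
            raise NetworkValidationError(
                f"self-loop on {edge.source!r} ({edge.kind}) is not allowed"
            )
        src_kind = nodes[edge.source].kind
        tgt_kind = nodes[edge.target].kind
        expected = {
            "ppi": ("protein", "protein"),
            "annotation": ("protein", "function"),
            "hierarchy": ("function", "function"),
        }[edge.kind]
        if edge.kind == "annotation":
            ok = {src_kind, tgt_kind} == {"protein", "function"}
        else:
            ok = (src_kind, tgt_kind) == expected
        if not ok:
            raise NetworkValidationError(
                f"edge {edge.source!r}->{edge.target!r}: kind {edge.kind!r} "
                f"incompatible with endpoint kinds ({src_kind}, {tgt_kind})"
            )
        edge = _canonical(edge, nodes)
        key = (edge.source, edge.target, edge.kind)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(edge)
    if n_dup:
        logger.warning("dropped %d duplicate edge(s); edges form a binary relation", n_dup)

    hier = nx.DiGraph()
    hier.add_edges_from(
        (e.source, e.target) for e in edges if e.kind == "hierarchy"
    )
    if hier.number_of_edges() and not nx.is_directed_acyclic_graph(hier):
        cycle = nx.find_cycle(hier)
        raise NetworkValidationError(
            f"function hierarchy contains a cycle: {[c[:2] for c in cycle]}"
        )

    edges.sort(key=lambda e: (e.kind, e.source, e.target))
    return MultiscaleNetwork(nodes=nodes, edges=edges)


@dataclass
class TransitionMatrix:
    """Row-stochastic biased walk matrix with an explicit dangling set.

    ``matrix[i, j]`` is the probability of stepping from node ``i`` to node
    ``j``; rows of nodes with no outgoing moves sum to 0 and their ordinals
    are collected in ``dangling``.
    """

    matrix: sparse.csr_matrix
    dangling: np.ndarray  # sorted ordinals of all-zero rows
    ids: list[str]
    kinds: np.ndarray

    def __post_init__(self) -> None:
        self.index = {nid: i for i, nid in enumerate(self.ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.ids)


def build_transition_matrix(
    net: MultiscaleNetwork, scheme: EdgeWeightScheme | None = None
) -> TransitionMatrix:
    """Derive the biased row-stochastic transition matrix from typed edges.

    Each typed edge contributes directed moves with a class weight:
    ``ppi`` both ways at ``scheme.ppi``; ``annotation`` protein→function at
    ``protein_to_function`` and back at ``function_to_protein``; ``hierarchy``
    child→parent at ``hierarchy_up`` and parent→child at ``hierarchy_down``.
    Row ``i`` is the weight-proportional distribution over node ``i``'s moves.
    """
    if net.n_nodes == 0:
        raise NetworkValidationError("cannot build a transition matrix for an empty network")
    scheme = scheme or EdgeWeightScheme()

    rows: list[int] = []
    cols: list[int] = []
    wts: list[float] = []

    def add(src: str, dst: str, w: float) -> None:
        rows.append(net.index[src])
        cols.append(net.index[dst])
        wts.append(w)

    for e in net.edges:
        if e.kind == "ppi":
            add(e.source, e.target, scheme.ppi)
            add(e.target, e.source, scheme.ppi)
        elif e.kind == "annotation":  # canonical: source is the protein
            add(e.source, e.target, scheme.protein_to_function)
            add(e.target, e.source, scheme.function_to_protein)
        else:  # hierarchy, child→parent
            add(e.source, e.target, scheme.hierarchy_up)
            add(e.target, e.source, scheme.hierarchy_down)

    n = net.n_nodes
    row_arr = np.asarray(rows, dtype=np.int64)
    col_arr = np.asarray(cols, dtype=np.int64)
    w_arr = np.asarray(wts, dtype=np.float64)
    row_sums = np.bincount(row_arr, weights=w_arr, minlength=n) if len(w_arr) else np.zeros(n)
    dangling = np.flatnonzero(row_sums == 0)
    probs = w_arr / row_sums[row_arr] if len(w_arr) else w_arr
    m = sparse.csr_matrix((probs, (row_arr, col_arr)), shape=(n, n))

    sums = np.asarray(m.sum(axis=1)).ravel()
    live = np.ones(n, dtype=bool)
    live[dangling] = False
    assert np.all(np.abs(sums[live] - 1.0) < 1e-12), "non-dangling rows must sum to 1"
    assert np.all(sums[~live] == 0.0)

    return TransitionMatrix(matrix=m, dangling=dangling, ids=list(net.ids), kinds=net.kinds())
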