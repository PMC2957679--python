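"""Graph data model and I/O for cellular interaction networks.

The two substrates of the analysis are an undirected protein-protein
interaction network (PPIN) and a directed transcription-regulatory network
(TRN).  Both are simple, unweighted graphs over opaque string identifiers:
no self-loops, no parallel edges, and no edge weights (interactions are
modelled as connected or unconnected).  :class:`Network` is a thin wrapper
around a :mod:`networkx` graph that enforces these invariants and carries
the directedness flag through the whole pipeline.

Supported on-disk dialects are 2-column tab/whitespace-delimited edge lists
(optional third column, e.g. a regulation sign, is parsed but ignored) and
SIF (``source  interaction-type  target [target ...]``).  GraphML export is
provided for visualisation tools such as Cytoscape.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkParseError",
    "UnknownNodeError",
    "load_network",
    "export_network",
    "shortest_paths",
    "distance_matrix",
    "adjacency_matrix",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list / SIF file cannot be parsed."""


class UnknownNodeError(KeyError):
    """Raised when an operation references a node absent from the network."""


class Network:
    """A simple unweighted graph (directed or undirected) over string ids.

    Invariants: no self-loops, no duplicate edges (an undirected edge is
    stored once regardless of input orientation), and every edge endpoint
    is a member of the node set.
    """

    __slots__ = ("g",)

    def __init__(self, graph: "nx.Graph | nx.DiGraph") -> None:
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        self.g = graph

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        directed: bool = False,
        nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network, silently deduplicating and dropping self-loops."""
        g: "nx.Graph | nx.DiGraph" = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(g)

    # -- basic queries ----------------------------------------------------

    @property
    def directed(self) -> bool:
        return self.g.is_directed()

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.g.nodes)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def has_node(self, v: str) -> bool:
        return self.g.has_node(v)

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    def edge_set(self) -> frozenset:
        """Edges as tuples; undirected edges are returned endpoint-sorted."""
        if self.directed:
            return frozenset(self.g.edges())
        return frozenset(tuple(sorted(e)) for e in self.g.edges())

    def node_order(self) -> List[str]:
        """Deterministic (sorted) node ordering used by matrix routines."""
        return sorted(self.g.nodes)

    def copy(self) -> "Network":
        return Network(self.g.copy())

    def __contains__(self, v: str) -> bool:
        return self.g.has_node(v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.nodes == other.nodes
            and self.edge_set() == other.edge_set()
        )

    def __hash__(self):  # mutable-ish container; identity hashing
        return id(self)

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<Network {kind}: {self.n_nodes} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# I/O


def _iter_data_rows(path: str) -> Iterator[Tuple[int, List[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def load_network(
    path: str,
    directed: bool = False,
    dialect: str = "tsv",
    node_list: Optional[str] = None,
) -> Network:
    """Load a network from a 2-column edge list (``tsv``) or ``sif`` file.

    Duplicate rows and self-loops are dropped with a logged count.  A
    third TSV column (e.g. a regulation sign on TRN edges) is ignored.
    ``node_list`` optionally names a one-column file of node ids so that
    isolated nodes survive loading.

    Raises :class:`NetworkParseError` on malformed rows (naming the line
    number) and on files with no data rows.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    g: "nx.Graph | nx.DiGraph" = nx.DiGraph() if directed else nx.Graph()
    n_dup = n_loop = n_rows = 0
    for lineno, fields in _iter_data_rows(path):
        n_rows += 1
        if dialect == "tsv":
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs = [(fields[0], fields[1])]
        else:  # sif
            if len(fields) == 1:  # isolated-node declaration
                g.add_node(fields[0])
                continue
            if len(fields) == 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF row has an interaction type "
                    "but no target"
                )
            pairs = [(fields[0], t) for t in fields[2:]]
        for u, v in pairs:
            if u == v:
                n_loop += 1
                g.add_node(u)
            elif g.has_edge(u, v):
                n_dup += 1
            else:
                g.add_edge(u, v)
    if n_rows == 0:
        raise NetworkParseError(f"{path}: no data rows")
    if node_list is not None:
        for _, fields in _iter_data_rows(node_list):
            g.add_node(fields[0])
    if n_dup or n_loop:
        logger.info(
            "load_network(%s): dropped %d duplicate edges, %d self-loops",
            path, n_dup, n_loop,
        )
    return Network(g)


def export_network(
    net: Network,
    path: str,
    fmt: str = "sif",
    annotations: Optional[Dict[str, dict]] = None,
    interaction: Optional[str] = None,
) -> None:
    """Write a network as SIF or GraphML.

    Round-trip property: ``load_network(export_network(net), dialect="sif")``
    reproduces the same node and edge sets.  ``annotations`` maps node id to
    an attribute dict (GraphML only).
    """
    if fmt == "sif":
        itype = interaction or ("reg" if net.directed else "pp")
        linked = set()
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(net.edge_set()):
                fh.write(f"{u}\t{itype}\t{v}\n")
                linked.update((u, v))
            for v in sorted(net.nodes - linked):
                fh.write(f"{v}\n")
    elif fmt == "graphml":
        g = net.g.copy()
        if annotations:
            nx.set_node_attributes(g, {k: dict(v) for k, v in annotations.items()})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


# ---------------------------------------------------------------------------
# Shortest-path primitives


def shortest_paths(net: Network, source: str) -> Dict[str, int]:
    """Unweighted BFS distances from ``source``; unreachable nodes absent.

    Directed networks follow edge direction only (outbound paths).
    """
    if source not in net:
        raise UnknownNodeError(source)
    return dict(nx.single_source_shortest_path_length(net.g, source))


def adjacency_matrix(net: Network) -> Tuple[np.ndarray, List[str]]:
    """Dense boolean adjacency in sorted-node order (row=source for directed)."""
    order = net.node_order()
    a = nx.to_numpy_array(net.g, nodelist=order, dtype=bool)
    return a, order


def distance_matrix(net: Network) -> Tuple[np.ndarray, List[str]]:
    """All-pairs unweighted shortest-path lengths (np.inf if unreachable).

    Row = source, column = target, in sorted-node order.  Backed by
    scipy.sparse.csgraph for speed; this matrix is the workhorse of the
    permutation engine (closeness and path-length statistics become pure
    array lookups).
    """
    order = net.node_order()
    n = len(order)
    if n == 0:
        return np.zeros((0, 0)), order
    a = sp.csr_matrix(nx.to_scipy_sparse_array(net.g, nodelist=order, dtype=np.int8))
    d = _csgraph_shortest_path(a, method="D", directed=net.directed, unweighted=True)
    return d, order
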