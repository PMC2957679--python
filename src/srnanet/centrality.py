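"""Node-level centrality metrics applied to single sRNA targets.

Four metrics are computed per target node: degree (split into in/out on the
directed TRN), closeness, betweenness, and the clustering coefficient.
Directed conventions follow the outbound rule — closeness and betweenness
consider only direction-respecting paths — and the clustering coefficient is
undefined on directed networks.

Conventions for fragmented networks: closeness averages over *reachable*
nodes only and is 0 for a node that reaches nobody; betweenness is the
fractional (shortest-path-multiplicity-weighted) count, normalised by
(n-1)(n-2)/2 undirected and (n-1)(n-2) directed so values lie in [0, 1];
the clustering coefficient of a degree<2 node is 0.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .network import Network, UnknownNodeError, distance_matrix, shortest_paths

__all__ = [
    "UndefinedMetricError",
    "degree",
    "closeness",
    "betweenness",
    "clustering_coefficient",
    "node_metrics_table",
    "metric_vectors",
    "NODE_METRICS_UNDIRECTED",
    "NODE_METRICS_DIRECTED",
]

NODE_METRICS_UNDIRECTED = ("degree", "closeness", "betweenness", "clustering_coefficient")
NODE_METRICS_DIRECTED = ("in_degree", "out_degree", "closeness", "betweenness")


class UndefinedMetricError(ValueError):
    """A metric was requested on a network type where it is undefined."""


def _check_node(net: Network, v: str) -> None:
    if v not in net:
        raise UnknownNodeError(v)


def degree(net: Network, v: str) -> Union[int, Tuple[int, int]]:
    """Neighbour count; on directed networks the (in, out) degree pair."""
    _check_node(net, v)
    if net.directed:
        return net.g.in_degree(v), net.g.out_degree(v)
    return net.g.degree(v)


def closeness(net: Network, v: str, harmonic: bool = False) -> float:
    """Reciprocal of the mean shortest-path distance from ``v`` to others.

    The mean is taken over reachable nodes only; an isolated node (or a
    directed node with no outbound paths) scores 0.  ``harmonic=True``
    switches to harmonic closeness (mean of reciprocal distances over all
    other nodes), which handles fragmentation without excluding anybody.
    """
    _check_node(net, v)
    dists = shortest_paths(net, v)
    dists.pop(v, None)
    if not dists:
        return 0.0
    if harmonic:
        return sum(1.0 / d for d in dists.values()) / max(net.n_nodes - 1, 1)
    return len(dists) / sum(dists.values())


def betweenness(net: Network, v: str) -> float:
    """Fraction of other-pair shortest paths passing through ``v``, in [0,1]."""
    _check_node(net, v)
    return nx.betweenness_centrality(net.g, normalized=True)[v]


def clustering_coefficient(net: Network, v: str) -> float:
    """Edges among v's neighbours over C(k,2); 0 when degree < 2.

    Undefined (raises) on directed networks.
    """
    _check_node(net, v)
    if net.directed:
        raise UndefinedMetricError("clustering coefficient is undefined on directed networks")
    return nx.clustering(net.g, v)


def node_metrics_table(
    net: Network,
    nodes: Iterable[str],
    harmonic: bool = False,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-node metric table plus per-metric means.

    Returns ``(table, means)``; means skip undefined entries and are NaN
    for an empty node list.  Raises :class:`UnknownNodeError` listing all
    offending ids if any node is absent from the network.
    """
    nodes = list(nodes)
    unknown = [v for v in nodes if v not in net]
    if unknown:
        raise UnknownNodeError(f"nodes not in network: {sorted(unknown)}")
    names = NODE_METRICS_DIRECTED if net.directed else NODE_METRICS_UNDIRECTED
    vectors, order = metric_vectors(net, names, harmonic=harmonic)
    idx = {v: i for i, v in enumerate(order)}
    rows = {
        "node": nodes,
        **{m: [vectors[m][idx[v]] for v in nodes] for m in names},
    }
    table = pd.DataFrame(rows)
    means = table[list(names)].mean() if nodes else pd.Series(
        {m: float("nan") for m in names}
    )
    return table, means


def metric_vectors(
    net: Network,
    metrics: Iterable[str],
    harmonic: bool = False,
    dist: Optional[np.ndarray] = None,
    order: Optional[List[str]] = None,
) -> Tuple[Dict[str, np.ndarray], List[str]]:
    """All-node metric value arrays in sorted-node order.

    Bulk counterpart of the scalar functions, used by the permutation
    engine so that a null replicate costs only an index-and-mean.  A
    precomputed distance matrix may be passed to avoid recomputation.
    """
    metrics = list(metrics)
    if order is None:
        order = net.node_order()
    n = len(order)
    out: Dict[str, np.ndarray] = {}
    need_dist = "closeness" in metrics
    if need_dist and dist is None:
        dist, order = distance_matrix(net)
    for m in metrics:
        if m == "degree":
            if net.directed:
                raise UndefinedMetricError("use in_degree/out_degree on directed networks")
            out[m] = np.array([net.g.degree(v) for v in order], dtype=float)
        elif m == "in_degree":
            out[m] = np.array([net.g.in_degree(v) for v in order], dtype=float)
        elif m == "out_degree":
            out[m] = np.array([net.g.out_degree(v) for v in order], dtype=float)
        elif m == "closeness":
            assert dist is not None
            vals = np.zeros(n)
            for i in range(n):
                row = dist[i]
                finite = np.isfinite(row)
                finite[i] = False
                r = int(finite.sum())
                if r > 0:
                    if harmonic:
                        vals[i] = (1.0 / row[finite]).sum() / max(n - 1, 1)
                    else:
                        vals[i] = r / row[finite].sum()
            out[m] = vals
        elif m == "betweenness":
            bc = nx.betweenness_centrality(net.g, normalized=True)
            out[m] = np.array([bc[v] for v in order])
        elif m == "clustering_coefficient":
            if net.directed:
                raise UndefinedMetricError(
                    "clustering coefficient is undefined on directed networks"
                )
            cc = nx.clustering(net.g)
            out[m] = np.array([cc[v] for v in order])
        else:
            raise ValueError(f"unknown node metric {m!r}")
    return out, order
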