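"""Per-sRNA subnet statistics: characteristic path length, density, IDR.

These statistics are evaluated each time on the set of all in-network
targets of a single sRNA ("the subnet").  An sRNA is *eligible* only when
at least two of its targets are in the network.  Density and the in-degree
ratio are legitimately 0 when no two targets interact; the characteristic
path length is undefined (NaN) when no target pair is connected, and is
only defined on undirected networks.

Directed conventions: the density denominator doubles to k(k-1) ordered
pairs; the in-degree ratio counts within-subnet arcs against arcs leaving
the subnet (outbound only).
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .centrality import UndefinedMetricError
from .network import Network, UnknownNodeError, shortest_paths

__all__ = [
    "IneligibleSubnetError",
    "characteristic_path_length",
    "subnet_density",
    "in_degree_ratio",
    "subnet_metrics_table",
    "SUBNET_METRICS_UNDIRECTED",
    "SUBNET_METRICS_DIRECTED",
]

SUBNET_METRICS_UNDIRECTED = ("cpl", "density", "in_degree_ratio")
SUBNET_METRICS_DIRECTED = ("density", "in_degree_ratio")


class IneligibleSubnetError(ValueError):
    """Fewer than two in-network targets: subnet statistics are not defined."""


def _check_targets(net: Network, targets: Iterable[str]) -> list:
    ts = sorted(set(targets))
    unknown = [t for t in ts if t not in net]
    if unknown:
        raise UnknownNodeError(f"targets not in network: {unknown}")
    if len(ts) < 2:
        raise IneligibleSubnetError(
            f"need at least two in-network targets, got {len(ts)}"
        )
    return ts


def characteristic_path_length(net: Network, targets: Iterable[str]) -> float:
    """Mean shortest-path length over connected target pairs (NaN if none)."""
    if net.directed:
        raise UndefinedMetricError(
            "characteristic path length is undefined on directed networks"
        )
    ts = _check_targets(net, targets)
    total = 0
    n_pairs = 0
    for i, u in enumerate(ts[:-1]):
        dists = shortest_paths(net, u)
        for v in ts[i + 1:]:
            if v in dists:
                total += dists[v]
                n_pairs += 1
    return total / n_pairs if n_pairs else float("nan")


def subnet_density(net: Network, targets: Iterable[str]) -> float:
    """Within-target edges over all possible: C(k,2), or k(k-1) directed."""
    ts = _check_targets(net, targets)
    k = len(ts)
    within = net.g.subgraph(ts).number_of_edges()
    denom = k * (k - 1) if net.directed else k * (k - 1) // 2
    return within / denom


def in_degree_ratio(net: Network, targets: Iterable[str]) -> float:
    """Within-subnet edges over edges leaving the subnet.

    Undirected: boundary edges are those with exactly one endpoint inside.
    Directed: within-arcs over arcs from a target to a non-target.
    Returns 0 when there are no within edges; NaN (undefined) when the
    boundary is empty but within edges exist.
    """
    ts = _check_targets(net, targets)
    tset = set(ts)
    within = net.g.subgraph(ts).number_of_edges()
    if net.directed:
        out_total = sum(net.g.out_degree(v) for v in ts)
        boundary = out_total - within
    else:
        deg_total = sum(net.g.degree(v) for v in ts)
        boundary = deg_total - 2 * within
    if within == 0:
        return 0.0
    if boundary == 0:
        return float("nan")
    return within / boundary


def subnet_metrics_table(
    net: Network,
    target_map,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-sRNA subnet statistics plus means over eligible sRNAs.

    ``target_map`` is an :class:`~srnanet.targets.TargetMap`.  Targets not
    present in the network are dropped before the in-network count ``k`` is
    computed; sRNAs with k < 2 are flagged ineligible and excluded from the
    means, as are undefined (NaN) cells.
    """
    names = SUBNET_METRICS_DIRECTED if net.directed else SUBNET_METRICS_UNDIRECTED
    rows = []
    for srna in sorted(target_map.srnas):
        ts = sorted(t for t in target_map.targets_of(srna) if t in net)
        k = len(ts)
        row = {"srna": srna, "n_targets_in_network": k, "eligible": k >= 2}
        for m in names:
            if k < 2:
                row[m] = float("nan")
            elif m == "cpl":
                row[m] = characteristic_path_length(net, ts)
            elif m == "density":
                row[m] = subnet_density(net, ts)
            else:
                row[m] = in_degree_ratio(net, ts)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["srna", "n_targets_in_network", "eligible", *names])
    if len(table):
        eligible = table[table["eligible"]]
        means = eligible[list(names)].mean()
    else:
        means = pd.Series({m: float("nan") for m in names})
    return table, means
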