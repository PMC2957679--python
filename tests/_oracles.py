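"""Independent brute-force oracles for the graph statistics.

Deliberately naive: Floyd-Warshall distances, geodesic counting via
adjacency-matrix powers, triple-loop triangle counting, exhaustive edge
classification.  These share no code with the package implementation.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def adjacency(nodes, edges, directed):
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n), dtype=np.int64)
    for u, v in edges:
        a[idx[u], idx[v]] = 1
        if not directed:
            a[idx[v], idx[u]] = 1
    return a, idx


def floyd_warshall(a):
    n = len(a)
    d = np.where(a > 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_degree(a, i, directed):
    if directed:
        return int(a[:, i].sum()), int(a[i, :].sum())
    return int(a[i, :].sum())


def oracle_closeness(d, i):
    row = np.delete(d[i], i)
    reach = row[np.isfinite(row)]
    if reach.size == 0:
        return 0.0
    return reach.size / reach.sum()


def geodesic_counts(a, d):
    """sigma[s, t] = number of shortest s->t paths, via matrix powers."""
    n = len(a)
    finite = d[np.isfinite(d)]
    max_d = int(finite.max()) if finite.size else 0
    powers = [np.eye(n, dtype=np.int64)]
    for _ in range(max_d):
        powers.append(powers[-1] @ a)
    sigma = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(d[s, t]):
                sigma[s, t] = powers[int(d[s, t])][s, t]
    return sigma


def oracle_betweenness(a, d, v, directed):
    n = len(a)
    sigma = geodesic_counts(a, d)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s == t or s == v or t == v:
                continue
            if not np.isfinite(d[s, t]):
                continue
            if np.isfinite(d[s, v]) and np.isfinite(d[v, t]) \
                    and d[s, v] + d[v, t] == d[s, t]:
                total += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if not directed:
        total /= 2.0  # ordered loop counts each unordered pair twice
        norm = (n - 1) * (n - 2) / 2.0
    else:
        norm = (n - 1) * (n - 2)
    return total / norm


def oracle_clustering(a, i):
    neigh = [j for j in range(len(a)) if a[i, j]]
    k = len(neigh)
    if k < 2:
        return 0.0
    links = sum(a[u, v] for u, v in combinations(neigh, 2))
    return links / (k * (k - 1) / 2)


def oracle_cpl(d, idxs):
    vals = [d[i, j] for i, j in combinations(sorted(idxs), 2)
            if np.isfinite(d[i, j])]
    return sum(vals) / len(vals) if vals else float("nan")


def oracle_density(a, idxs, directed):
    idxs = sorted(idxs)
    k = len(idxs)
    if directed:
        within = sum(int(a[i, j]) for i in idxs for j in idxs if i != j)
        return within / (k * (k - 1))
    within = sum(int(a[i, j]) for i, j in combinations(idxs, 2))
    return within / (k * (k - 1) / 2)


def oracle_idr(a, idxs, directed):
    inside = set(idxs)
    n = len(a)
    if directed:
        within = sum(int(a[i, j]) for i in inside for j in inside if i != j)
        out = sum(int(a[i, j]) for i in inside for j in range(n)
                  if j not in inside)
    else:
        within = sum(int(a[i, j]) for i, j in combinations(sorted(inside), 2))
        out = sum(int(a[i, j]) for i in inside for j in range(n)
                  if j not in inside)
    if within == 0:
        return 0.0
    if out == 0:
        return float("nan")
    return within / out
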