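"""Independent brute-force oracles for the graph metrics.

Deliberately different algorithms from the package implementation:
distances via Floyd-Warshall, shortest-path counts via walk-counting on
adjacency powers, through-counts via explicit path enumeration, clustering
via a triple loop. Slow but unambiguous.
"""

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def distances_oracle(adj):
    return floyd_warshall(np.asarray(adj, dtype=float), directed=False,
                          unweighted=True)


def sigma_oracle(adj):
    """Number of shortest paths between every pair: walks of minimal length
    counted by matrix powers (a walk of the shortest length is simple)."""
    a = np.asarray(adj, dtype=np.int64)
    n = a.shape[0]
    dist = distances_oracle(a)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    power = np.eye(n, dtype=np.int64)
    max_finite = int(dist[np.isfinite(dist)].max()) if np.isfinite(dist).any() else 0
    for length in range(1, max_finite + 1):
        power = power @ a
        sigma[dist == length] = power[dist == length]
    return sigma


def enumerate_shortest_paths(adj, start, end, dist):
    """Yield every shortest path start->end as a node tuple (DFS guided by
    the distance matrix; each emitted path is an explicit simple path)."""
    if not np.isfinite(dist[start, end]):
        return
    a = np.asarray(adj)

    def extend(path):
        last = path[-1]
        if last == end:
            yield tuple(path)
            return
        remaining = dist[last, end]
        for nxt in np.nonzero(a[last])[0]:
            if dist[nxt, end] == remaining - 1:
                yield from extend(path + [nxt])

    yield from extend([start])


def through_counts_oracle(adj, i):
    """sigma_jk(i) for interior node i by path enumeration."""
    a = np.asarray(adj)
    n = a.shape[0]
    dist = distances_oracle(a)
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k or i in (j, k) or not np.isfinite(dist[j, k]):
                continue
            out[j, k] = sum(1 for p in enumerate_shortest_paths(a, j, k, dist)
                            if i in p[1:-1])
    return out


def clustering_oracle(adj):
    a = np.asarray(adj)
    n = a.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k < 2:
            continue
        tri = 0
        nbrs = np.nonzero(a[i])[0]
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                if a[nbrs[x], nbrs[y]]:
                    tri += 1
        cc[i] = 2.0 * tri / (k * (k - 1))
    return cc


def cpl_oracle(adj, policy="reachable"):
    dist = distances_oracle(adj)
    n = dist.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        d = np.delete(dist[i], i)
        if policy == "literal":
            out[i] = d.mean() if np.isfinite(d).all() else np.inf
        else:
            finite = d[np.isfinite(d)]
            out[i] = finite.mean() if finite.size else np.nan
    return out


def betweenness_oracle(adj):
    """Normalised betweenness from enumerated path counts."""
    a = np.asarray(adj)
    n = a.shape[0]
    dist = distances_oracle(a)
    sigma = sigma_oracle(a)
    bc = np.zeros(n)
    if n < 3:
        return bc
    for i in range(n):
        tc = through_counts_oracle(a, i)
        total = 0.0
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or sigma[j, k] == 0:
                    continue
                total += tc[j, k] / sigma[j, k]
        bc[i] = 2.0 * total / ((n - 1) * (n - 2))
    return bc
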