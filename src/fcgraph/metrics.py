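"""Node-level metrics on binary undirected graphs.

All operations work on dense 0/1 adjacency matrices (``numpy`` arrays or the
:class:`~fcgraph.connectivity.AdjacencyMatrix` wrapper). Four metrics are
provided: degree (``D``), clustering coefficient (``CC``), characteristic
path length (``CPL``) and betweenness centrality (``BC``). Path-dependent
metrics share one breadth-first shortest-path pass per graph.

Conventions
-----------
* ``CC`` uses unordered neighbour pairs, so a triangle has ``CC = 1``; nodes
  with degree < 2 get ``CC = 0``.
* ``BC`` is normalised by ``(N-1)(N-2)/2`` unordered pairs, so it lies in
  ``[0, 1]``; for ``N < 3`` it is defined as 0.
* ``CPL`` averages hop distances to the other nodes. Policy ``"reachable"``
  (default) averages over reachable nodes only and flags isolated nodes as
  undefined; policy ``"literal"`` propagates infinity when any node is
  unreachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

METRIC_NAMES = ("D", "CC", "CPL", "BC")

CPL_POLICIES = ("reachable", "literal")


def as_adjacency_array(adj) -> np.ndarray:
    """Unwrap/validate a binary undirected adjacency matrix.

    Accepts a square array-like of 0/1 entries or any object with a
    ``values`` attribute holding one. Raises ``ValueError`` on asymmetry,
    nonzero diagonal or entries outside {0, 1}.
    """
    if hasattr(adj, "values") and not isinstance(adj, np.ndarray):
        adj = adj.values
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    a = a.astype(float)
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    if np.diag(a).any():
        raise ValueError("adjacency diagonal must be zero")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a


@dataclass
class MetricVector:
    """Per-node values of one graph metric."""

    metric: str
    values: np.ndarray
    undefined: np.ndarray = None  # boolean mask; None means all defined
    node_ids: np.ndarray = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = np.zeros(self.values.shape, dtype=bool)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ShortestPathData:
    """All-pairs BFS results on a binary graph.

    ``lengths[j, k]`` is the hop count of the shortest path (``inf`` when
    unreachable, 0 on the diagonal); ``sigma[j, k]`` the number of distinct
    shortest paths (``sigma[j, j] = 1``); ``dependency[i]`` the Brandes
    dependency accumulated over ordered source/target pairs, i.e.
    ``sum_{j != i != k} sigma_jk(i) / sigma_jk`` counting (j, k) and (k, j).
    """

    lengths: np.ndarray
    sigma: np.ndarray
    dependency: np.ndarray

    @property
    def n(self) -> int:
        return self.lengths.shape[0]

    def through_counts(self, i: int) -> np.ndarray:
        """Number of shortest j->k paths passing through interior node ``i``.

        Uses the composition identity
        ``sigma_jk(i) = sigma_ji * sigma_ik`` iff ``l_ji + l_ik = l_jk``.
        Entries with ``j == i``, ``k == i`` or ``j == k`` are 0.
        """
        li = self.lengths[i]
        with np.errstate(invalid="ignore"):
            on_path = li[:, None] + li[None, :] == self.lengths
        tc = np.where(on_path, self.sigma[:, i, None] * self.sigma[None, i, :], 0.0)
        tc[i, :] = 0.0
        tc[:, i] = 0.0
        np.fill_diagonal(tc, 0.0)
        return tc


def degree(adj) -> MetricVector:
    """Number of connections of each node (row sums of the adjacency)."""
    a = as_adjacency_array(adj)
    return MetricVector("D", a.sum(axis=1))


def clustering(adj) -> MetricVector:
    """Fraction of each node's neighbour pairs that are themselves linked.

    ``CC_i = 2 T_i / (k_i (k_i - 1))`` with ``T_i`` the number of triangles
    at ``i``; 0 by convention when ``k_i < 2``.
    """
    a = as_adjacency_array(adj)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return MetricVector("CC", cc)


def shortest_paths(adj) -> ShortestPathData:
    """BFS from every source with shortest-path counting.

    Brandes-style dependency accumulation is folded into the same pass so
    betweenness needs no second traversal.
    """
    a = as_adjacency_array(adj).astype(bool)
    n = a.shape[0]
    lengths = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    dependency = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sig = np.zeros(n)
        dist[s] = 0.0
        sig[s] = 1.0
        seen = np.zeros(n, dtype=bool)
        seen[s] = True
        levels = [np.array([s])]
        while True:
            cur = levels[-1]
            nxt_mask = a[cur].any(axis=0) & ~seen
            if not nxt_mask.any():
                break
            nxt = np.nonzero(nxt_mask)[0]
            sig[nxt] = a[np.ix_(nxt, cur)] @ sig[cur]
            dist[nxt] = len(levels)
            seen[nxt] = True
            levels.append(nxt)
        delta = np.zeros(n)
        for d in range(len(levels) - 1, 0, -1):
            w = levels[d]
            coeff = (1.0 + delta[w]) / sig[w]
            v = levels[d - 1]
            delta[v] += sig[v] * (a[np.ix_(v, w)] @ coeff)
        delta[s] = 0.0
        dependency += delta
        lengths[s] = dist
        sigma[s] = sig
    return ShortestPathData(lengths, sigma, dependency)


def char_path_length(spd: ShortestPathData, policy: str = "reachable") -> MetricVector:
    """Average shortest-path length from each node to the others.

    ``policy="literal"`` propagates infinite distances; ``"reachable"``
    averages over reachable targets only, flags isolated nodes as undefined
    (NaN) and records per-node unreachable counts in ``info``.
    """
    if policy not in CPL_POLICIES:
        raise ValueError(f"unknown CPL policy {policy!r}; choose from {CPL_POLICIES}")
    n = spd.n
    off = ~np.eye(n, dtype=bool)
    L = spd.lengths
    if n < 2:
        return MetricVector("CPL", np.full(n, np.nan),
                            undefined=np.ones(n, dtype=bool),
                            info={"policy": policy})
    if policy == "literal":
        vals = np.where(np.isfinite(L).all(axis=1, where=off),
                        L.sum(axis=1, where=off) / (n - 1), np.inf)
        undefined = np.zeros(n, dtype=bool)
        unreachable = (~np.isfinite(L) & off).sum(axis=1)
    else:
        finite = np.isfinite(L) & off
        count = finite.sum(axis=1)
        total = np.where(finite, L, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(count > 0, total / count, np.nan)
        undefined = count == 0
        unreachable = (n - 1) - count
    return MetricVector("CPL", vals, undefined=undefined,
                        info={"policy": policy,
                              "unreachable_counts": unreachable})


def betweenness(spd: ShortestPathData) -> MetricVector:
    """Normalised betweenness centrality in ``[0, 1]``.

    ``BC_i = 2 / ((N-1)(N-2)) * sum over unordered pairs {j, k}`` of the
    fraction of shortest j-k paths passing through ``i``.
    """
    n = spd.n
    if n < 3:
        warnings.warn("betweenness undefined for N < 3; returning zeros",
                      stacklevel=2)
        return MetricVector("BC", np.zeros(n))
    # dependency counts ordered pairs, i.e. twice the unordered sum
    return MetricVector("BC", spd.dependency / ((n - 1.0) * (n - 2.0)))


def all_metrics(adj, cpl_policy: str = "reachable",
                node_ids=None) -> dict[str, MetricVector]:
    """Compute D, CC, CPL and BC with a single shortest-path pass."""
    a = as_adjacency_array(adj)
    spd = shortest_paths(a)
    out = {
        "D": degree(a),
        "CC": clustering(a),
        "CPL": char_path_length(spd, policy=cpl_policy),
        "BC": betweenness(spd),
    }
    if node_ids is not None:
        ids = np.asarray(node_ids)
        for mv in out.values():
            mv.node_ids = ids
    return out
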