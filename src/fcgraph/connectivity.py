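"""From node time series to binary functional-connectivity graphs.

Stages: motion-scrubbing exclusion check, per-node autoregressive
prewhitening, Pearson correlation, proportional thresholding (keep the top
fraction of connections) and group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

INCLUDE = "include"
EXCLUDE = "exclude"

SCRUB_LIMIT = 30  # volumes; exclusion is strict ("more than")

RANK_MODES = ("signed", "absolute")


@dataclass
class TimeSeriesMatrix:
    """One subject-session's T x N node signals (rows = time points)."""

    data: np.ndarray
    subject_id: str = ""
    session: int = 1
    node_ids: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D T x N array")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.node_ids is None:
            self.node_ids = np.arange(1, self.data.shape[1] + 1)
        else:
            self.node_ids = np.asarray(self.node_ids)
            if self.node_ids.size != self.data.shape[1]:
                raise ValueError("node_ids length does not match column count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class AdjacencyMatrix:
    """Binary undirected graph with bookkeeping from thresholding."""

    values: np.ndarray
    density: float
    n_edges: int
    ties_at_cutoff: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def scrub_check(censored_volume_count: int, limit: int = SCRUB_LIMIT) -> str:
    """Movement exclusion rule: exclude iff strictly more than ``limit``
    volumes were discarded."""
    if censored_volume_count < 0:
        raise ValueError("censored volume count must be non-negative")
    if limit < 0:
        raise ValueError("scrub limit must be non-negative")
    return EXCLUDE if censored_volume_count > limit else INCLUDE


def _fit_ar_residuals(x: np.ndarray, max_order: int) -> tuple[np.ndarray, int]:
    """AR(p) prewhitening of one demeaned series, order chosen by AIC.

    Orders 0..max_order are compared on the common sample t >= max_order
    (same effective length, so AICs are comparable); the winning order is
    then used to compute residuals over t >= p. The first p output values
    are the demeaned input (conditioning-on-initial-values padding), so the
    output length equals the input length.
    """
    t = x.size
    mu = x.mean()
    xc = x - mu
    max_order = int(min(max_order, t // 3))
    n_eff = t - max_order
    best = (np.inf, 0, None)
    y = xc[max_order:]
    for p in range(max_order + 1):
        if p == 0:
            rss = float(y @ y)
            phi = np.empty(0)
        else:
            X = np.column_stack([xc[max_order - k: t - k] for k in range(1, p + 1)])
            phi, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ phi
            rss = float(r @ r)
        aic = n_eff * np.log(max(rss, 1e-300) / n_eff) + 2.0 * (p + 1)
        if aic < best[0]:
            best = (aic, p, phi)
    _, p, phi = best
    resid = xc.copy()
    if p > 0:
        X = np.column_stack([xc[p - k: t - k] for k in range(1, p + 1)])
        # refit on the full usable sample at the selected order
        phi, *_ = np.linalg.lstsq(X, xc[p:], rcond=None)
        resid[p:] = xc[p:] - X @ phi
    return resid, p


def prewhiten(series: TimeSeriesMatrix, max_order: int = 10) -> TimeSeriesMatrix:
    """Remove temporal autocorrelation from every node's series.

    Per column an AR(p) model with p in [0, max_order] selected by AIC is
    fitted and the residual series returned (length preserved; the first p
    samples are passed through demeaned). Selected orders are recorded in
    ``meta["ar_orders"]``.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    data = series.data
    spans = np.ptp(data, axis=0)
    if (spans == 0).any():
        bad = series.node_ids[np.nonzero(spans == 0)[0][0]]
        raise ValueError(f"constant time series at node {bad}: cannot prewhiten")
    out = np.empty_like(data)
    orders = np.empty(data.shape[1], dtype=int)
    for j in range(data.shape[1]):
        out[:, j], orders[j] = _fit_ar_residuals(data[:, j], max_order)
    meta = dict(series.meta)
    meta["ar_orders"] = orders
    return TimeSeriesMatrix(out, subject_id=series.subject_id,
                            session=series.session,
                            node_ids=series.node_ids, meta=meta)


def pearson_matrix(series: TimeSeriesMatrix | np.ndarray) -> np.ndarray:
    """Sample Pearson correlation between all node pairs (exactly symmetric,
    unit diagonal)."""
    data = series.data if isinstance(series, TimeSeriesMatrix) else np.asarray(series, float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    spans = np.ptp(data, axis=0)
    if (spans == 0).any():
        j = int(np.nonzero(spans == 0)[0][0])
        raise ValueError(f"zero-variance column at index {j}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def proportional_threshold(conn: np.ndarray, density: float = 0.20,
                           mode: str = "signed") -> AdjacencyMatrix:
    """Keep the strongest fraction of connections as binary edges.

    ``E = round(density * N(N-1)/2)`` upper-triangle entries with the
    largest correlations become edges (mirrored into a symmetric 0/1 matrix
    with zero diagonal). ``mode="signed"`` ranks by the raw correlation
    (default); ``"absolute"`` by magnitude. Ties at the cutoff are broken by
    (i, j) lexicographic order, so the result is deterministic.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    if mode not in RANK_MODES:
        raise ValueError(f"unknown ranking mode {mode!r}; choose from {RANK_MODES}")
    c = np.asarray(conn, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("connectivity matrix must be square")
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = c[iu, ju]
    if mode == "absolute":
        vals = np.abs(vals)
    m = vals.size
    n_edges = int(np.floor(density * m + 0.5))  # round half away from zero
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    ties = 0
    if 0 < n_edges < m:
        cutoff = vals[order[n_edges - 1]]
        ties = int((vals == cutoff).sum()) - 1
    return AdjacencyMatrix(adj, density=n_edges / m if m else 0.0,
                           n_edges=n_edges, ties_at_cutoff=ties)


def group_average(conns: list[np.ndarray], fisher: bool = False) -> np.ndarray:
    """Elementwise mean connectivity matrix across subjects.

    ``fisher=True`` averages on the arctanh scale and transforms back
    (off by default: the plain mean is the literal procedure).
    """
    if len(conns) == 0:
        raise ValueError("cannot average an empty list of matrices")
    mats = [np.asarray(c, dtype=float) for c in conns]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all connectivity matrices must share one shape")
    stack = np.stack(mats)
    if fisher:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        return np.tanh(z.mean(axis=0))
    return stack.mean(axis=0)


# ---------------------------------------------------------------------------
# plain-text I/O

def load_timeseries(path, subject_id: str = "", session: int = 1) -> TimeSeriesMatrix:
    """Read a delimited T x N time-series file (header row of node ids)."""
    df = pd.read_csv(path, sep=None, engine="python")
    try:
        node_ids = np.array([int(c) for c in df.columns])
    except ValueError:
        node_ids = df.columns.to_numpy()
    return TimeSeriesMatrix(df.to_numpy(dtype=float), subject_id=subject_id,
                            session=session, node_ids=node_ids)


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, float), fmt="%.10g", delimiter=",")


def load_matrix_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_edge_list(adj: AdjacencyMatrix | np.ndarray, path, node_ids=None) -> None:
    """Upper-triangle edge list ``i,j`` with 1-based node ids."""
    a = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    n = a.shape[0]
    ids = np.asarray(node_ids) if node_ids is not None else np.arange(1, n + 1)
    iu, ju = np.triu_indices(n, k=1)
    mask = a[iu, ju] > 0
    with open(path, "w") as fh:
        fh.write("i,j\n")
        for i, j in zip(ids[iu[mask]], ids[ju[mask]]):
            fh.write(f"{i},{j}\n")
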