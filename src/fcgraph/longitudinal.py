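"""Relative metric change between sessions, display filtering and
region-level increase/decrease summaries.

The change measure is the dimensionless fraction ``(M2 - M1) / M1`` per
node; nodes with ``M1 = 0`` are flagged undefined and excluded downstream.
A node is *shown* when its absolute change exceeds half the mean absolute
change over all defined nodes (the rule used to blank small variations on
the published maps; the absolute-value reading is an interpretation —
see the package README).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricVector


@dataclass
class DeltaMetricVector:
    """Per-node relative change of one metric between two sessions."""

    metric: str
    values: np.ndarray          # NaN where undefined
    undefined: np.ndarray
    node_ids: np.ndarray = None
    label: str = ""             # subject or group identifier
    info: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return ~self.undefined

    @property
    def n(self) -> int:
        return self.values.size


def delta_metric(m1: MetricVector, m2: MetricVector, label: str = "") -> DeltaMetricVector:
    """Relative change ``(M2 - M1) / M1`` per node.

    Nodes where ``M1 == 0`` or either session's value is undefined or
    non-finite are flagged undefined (NaN).
    """
    if m1.metric != m2.metric:
        raise ValueError(f"metric mismatch: {m1.metric!r} vs {m2.metric!r}")
    if m1.values.shape != m2.values.shape:
        raise ValueError("metric vectors have different lengths")
    v1, v2 = m1.values, m2.values
    undefined = (m1.undefined | m2.undefined
                 | ~np.isfinite(v1) | ~np.isfinite(v2) | (v1 == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dm = np.where(undefined, np.nan, (v2 - v1) / np.where(v1 == 0, np.nan, v1))
    node_ids = m1.node_ids if m1.node_ids is not None else None
    return DeltaMetricVector(m1.metric, dm, undefined, node_ids=node_ids, label=label)


def display_filter(delta: DeltaMetricVector) -> np.ndarray:
    """Boolean mask of nodes whose variation is large enough to display.

    A node is shown iff ``|dM_i| > 0.5 * mean(|dM|)`` over defined nodes.
    All-undefined input yields an empty (all-False) mask with a warning.
    """
    shown = np.zeros(delta.n, dtype=bool)
    defined = delta.defined
    if not defined.any():
        warnings.warn("display_filter: no defined changes; nothing shown",
                      stacklevel=2)
        return shown
    absdm = np.abs(delta.values[defined])
    threshold = 0.5 * absdm.mean()
    shown[defined] = np.abs(delta.values[defined]) > threshold
    return shown


def region_aggregate(delta: DeltaMetricVector, node_region_map: pd.DataFrame,
                     shown: np.ndarray) -> pd.DataFrame:
    """Summarise shown changes per (region, side).

    A region is tagged ``increase`` if any of its shown nodes increased and
    ``decrease`` if any decreased — both tags may coexist (changes in
    distinct nodes of the same region). Regions with no shown nodes are
    absent. Returns columns ``region, side, increase, decrease, tags,
    n_nodes, mean_delta, node_ids``.
    """
    if delta.node_ids is None:
        node_ids = np.arange(1, delta.n + 1)
    else:
        node_ids = np.asarray(delta.node_ids)
    mp = node_region_map.set_index("node_id")
    rows = {}
    skipped_unmapped = 0
    for idx, nid in enumerate(node_ids):
        if not shown[idx] or delta.undefined[idx]:
            continue
        if nid not in mp.index or not bool(mp.at[nid, "mapped"]):
            skipped_unmapped += 1
            continue
        key = (mp.at[nid, "region"], mp.at[nid, "side"])
        rows.setdefault(key, []).append((nid, float(delta.values[idx])))
    recs = []
    for (region, side), entries in rows.items():
        vals = np.array([v for _, v in entries])
        inc, dec = bool((vals > 0).any()), bool((vals < 0).any())
        tags = ("↑" if inc else "") + ("," if inc and dec else "") + ("↓" if dec else "")
        recs.append({
            "region": region, "side": side,
            "increase": inc, "decrease": dec, "tags": tags,
            "n_nodes": len(entries),
            "mean_delta": float(vals.mean()),
            "node_ids": ";".join(str(n) for n, _ in entries),
        })
    out = pd.DataFrame(recs, columns=["region", "side", "increase", "decrease",
                                      "tags", "n_nodes", "mean_delta", "node_ids"])
    out = out.sort_values(["region", "side"]).reset_index(drop=True)
    out.attrs["skipped_unmapped"] = skipped_unmapped
    return out


def hemisphere_split(delta: DeltaMetricVector, node_region_map: pd.DataFrame,
                     shown: np.ndarray, node_table: pd.DataFrame) -> dict:
    """Per-hemisphere region summaries, assuming lesions pre-flipped right.

    ``IL`` (ipsilesional) collects nodes with x > 0, ``CL`` (contralesional)
    nodes with x < 0; midline nodes (x == 0) belong to neither and are
    counted separately.
    """
    x = node_table.set_index("node_id")["x"]
    if delta.node_ids is None:
        node_ids = np.arange(1, delta.n + 1)
    else:
        node_ids = np.asarray(delta.node_ids)
    xs = np.array([float(x.get(n, np.nan)) for n in node_ids])
    out = {}
    for hemi, mask in (("IL", xs > 0), ("CL", xs < 0)):
        out[hemi] = region_aggregate(delta, node_region_map, shown & mask)
    out["midline_count"] = int((xs == 0).sum())
    return out


def delta_to_frame(delta: DeltaMetricVector, shown: np.ndarray = None) -> pd.DataFrame:
    """Tidy per-node export: label, metric, node_id, delta, defined, shown."""
    node_ids = (np.asarray(delta.node_ids) if delta.node_ids is not None
                else np.arange(1, delta.n + 1))
    df = pd.DataFrame({
        "label": delta.label,
        "metric": delta.metric,
        "node_id": node_ids,
        "delta": delta.values,
        "defined": delta.defined,
    })
    if shown is not None:
        df["shown"] = shown
    return df
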