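"""Clinical-table handling and the brain-behaviour correlation analysis.

Group assignment from first-visit Rankin/Barthel scores, motor-score deltas,
ROI-averaged betweenness change, and the per-ROI correlation of average
betweenness change against upper-extremity motor recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MOTOR = "motor"
CONTROL = "control"
UNCLASSIFIED = "unclassified"

UEFM_MAX = 66
LEFM_MAX = 34

CLINICAL_COLUMNS = [
    "subject_id", "group", "lesion_side",
    "rankin_t1", "rankin_t2", "barthel_t1", "barthel_t2", "nihss",
    "uefm_t1", "uefm_t2", "lefm_t1", "lefm_t2",
]


@dataclass
class CorrelationResult:
    """One ROI x hemisphere association test."""

    roi: str
    hemisphere: str
    n: int
    r: float
    p: float
    significant: bool
    method: str = "pearson"
    p_adjusted: float = None


def assign_group(rankin, barthel) -> str:
    """Classify a subject from first-visit functionality scores.

    Control: Rankin 0 or 1 AND Barthel 100. Motor: Rankin >= 1 AND
    Barthel < 100. The rule leaves Rankin 0 with Barthel < 100 undefined;
    such records are flagged ``unclassified`` rather than binned.
    """
    if rankin is None or barthel is None or (
            isinstance(rankin, float) and math.isnan(rankin)) or (
            isinstance(barthel, float) and math.isnan(barthel)):
        raise ValueError("group assignment needs both Rankin and Barthel scores")
    if not 0 <= rankin <= 5:
        raise ValueError(f"Rankin score {rankin} outside 0-5")
    if not 0 <= barthel <= 100:
        raise ValueError(f"Barthel score {barthel} outside 0-100")
    if rankin in (0, 1) and barthel == 100:
        return CONTROL
    if rankin >= 1 and barthel < 100:
        return MOTOR
    return UNCLASSIFIED


def assign_groups(clinical: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_group` over a clinical table (t1 scores)."""
    return clinical.apply(
        lambda row: assign_group(row["rankin_t1"], row["barthel_t1"]), axis=1)


def delta_uefm(uefm_t1, uefm_t2) -> float:
    """Upper-extremity motor score change (second minus first visit)."""
    for name, v in (("uefm_t1", uefm_t1), ("uefm_t2", uefm_t2)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing score {name}")
        if not 0 <= v <= UEFM_MAX:
            raise ValueError(f"{name}={v} outside 0-{UEFM_MAX}")
    return float(uefm_t2) - float(uefm_t1)


def roi_mean_delta_bc(delta, roi_nodes) -> float:
    """Arithmetic mean betweenness change over an ROI's defined nodes.

    ``delta`` is a :class:`~fcgraph.longitudinal.DeltaMetricVector`;
    ``roi_nodes`` a set of node ids. Returns NaN (flagged missing) when no
    defined node of the ROI is present.
    """
    node_ids = (np.asarray(delta.node_ids) if delta.node_ids is not None
                else np.arange(1, delta.n + 1))
    sel = np.isin(node_ids, list(roi_nodes)) & delta.defined
    if not sel.any():
        return float("nan")
    return float(delta.values[sel].mean())


def correlate_roi(deltas, scores, alpha: float = 0.05, method: str = "pearson",
                  roi: str = "", hemisphere: str = "") -> CorrelationResult:
    """Correlate per-subject ROI-average metric changes with score changes.

    Pearson by default (two-sided p from the exact t transform with n-2
    degrees of freedom); ``method="spearman"`` available. Pairs with a
    missing value on either side are dropped listwise.
    """
    x = np.asarray(deltas, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("deltas and scores must be paired 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(roi=roi, hemisphere=hemisphere, n=n,
                             r=float(r), p=float(p),
                             significant=bool(p < alpha), method=method)


def holm_adjust(results: list[CorrelationResult], alpha: float = 0.05) -> None:
    """Holm step-down familywise correction across a result family
    (in place: fills ``p_adjusted`` and re-derives ``significant``)."""
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * results[idx].p)
        running = max(running, adj)
        results[idx].p_adjusted = running
        results[idx].significant = bool(running < alpha)


def run_fig5_analysis(panel_means: pd.DataFrame, scores: pd.Series,
                      alpha: float = 0.05, method: str = "pearson",
                      correction: str = "none") -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Per-(ROI, hemisphere) correlation of ROI-average betweenness change
    with motor-score change.

    ``panel_means`` is tidy with columns ``subject_id, roi, hemisphere,
    mean_dbc``; ``scores`` maps subject_id -> score change. Subjects with a
    missing value in a panel are dropped from that panel (listwise). Returns
    the result list plus the per-panel scatter data.
    """
    if correction not in ("none", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    results = []
    scatter_rows = []
    panels = panel_means.groupby(["roi", "hemisphere"], sort=True)
    for (roi, hemi), grp in panels:
        xs, ys, subs = [], [], []
        for _, row in grp.iterrows():
            s = scores.get(row["subject_id"], float("nan"))
            xs.append(row["mean_dbc"])
            ys.append(s)
            subs.append(row["subject_id"])
        for sub, xv, yv in zip(subs, xs, ys):
            scatter_rows.append({"roi": roi, "hemisphere": hemi,
                                 "subject_id": sub, "mean_dbc": xv,
                                 "delta_uefm": yv})
        try:
            results.append(correlate_roi(xs, ys, alpha=alpha, method=method,
                                         roi=roi, hemisphere=hemi))
        except ValueError as exc:
            # degenerate panel (too few valid pairs / constant input):
            # surfaced as an undefined result rather than aborting the family
            warnings.warn(f"panel {roi}/{hemi}: {exc}", stacklevel=2)
            n_valid = int(np.sum(np.isfinite(np.asarray(xs, dtype=float))
                                 & np.isfinite(np.asarray(ys, dtype=float))))
            results.append(CorrelationResult(
                roi=roi, hemisphere=hemi, n=n_valid,
                r=float("nan"), p=float("nan"), significant=False,
                method=method))
    if correction == "holm":
        holm_adjust(results, alpha=alpha)
    scatter = pd.DataFrame(scatter_rows)
    return results, scatter


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "roi": r.roi, "hemisphere": r.hemisphere, "n": r.n,
        "r": r.r, "p": r.p, "significant": r.significant,
        "method": r.method, "p_adjusted": r.p_adjusted,
    } for r in results], columns=["roi", "hemisphere", "n", "r", "p",
                                 "significant", "method", "p_adjusted"])
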