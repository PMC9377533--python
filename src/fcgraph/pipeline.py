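"""End-to-end orchestration: cohort -> graphs -> metrics -> change maps ->
region summaries -> behaviour correlation.

Two labelled paths coexist, mirroring the analysis design:

* *group path* — per-group average connectivity per session, thresholded,
  metric change maps, display filter, hemisphere-wise region summaries;
* *individual path* — per-subject betweenness change, ROI-averaged and
  correlated with upper-extremity motor-score change across the motor group.

Inputs at this stage are node-level and assumed lesion-oriented (any image
flip happens upstream of node-series extraction); set ``flip_left_lesions``
to mirror node coordinates per subject before anatomical attribution when
ingesting unoriented tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas, clinical, connectivity, longitudinal, metrics
from .clinical import MOTOR
from .connectivity import INCLUDE, scrub_check
from .synth import SyntheticCohort


@dataclass
class PipelineConfig:
    density: float = 0.20
    rank_mode: str = "signed"       # or "absolute"
    cpl_policy: str = "reachable"   # or "literal"
    alpha: float = 0.05
    correction: str = "none"        # or "holm"
    method: str = "pearson"         # or "spearman"
    do_prewhiten: bool = True
    max_order: int = 10
    max_distance: float = atlas.DEFAULT_MAX_DISTANCE
    scrub_limit: int = connectivity.SCRUB_LIMIT
    fisher_average: bool = False
    flip_left_lesions: bool = False
    roi_spec: dict = None
    region_table: pd.DataFrame = None

    def __post_init__(self):
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GroupResult:
    group: str
    n_subjects: int
    session_metrics: dict            # session -> {metric -> MetricVector}
    deltas: dict                     # metric -> DeltaMetricVector
    shown: dict                      # metric -> boolean mask
    summaries: dict                  # metric -> {"IL": df, "CL": df, "midline_count": int}
    adjacency_info: dict = field(default_factory=dict)


@dataclass
class CohortResults:
    config: PipelineConfig
    included: list
    excluded: list
    group_results: dict              # group -> GroupResult
    fig5_results: list               # CorrelationResult per ROI x hemisphere
    fig5_scatter: pd.DataFrame
    panel_means: pd.DataFrame
    subject_bc_delta: dict           # subject_id -> DeltaMetricVector
    connectivities: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def subject_connectivity(ts, cfg: PipelineConfig) -> np.ndarray:
    """Prewhiten (optional) then Pearson-correlate one session."""
    if cfg.do_prewhiten:
        ts = connectivity.prewhiten(ts, max_order=cfg.max_order)
    return connectivity.pearson_matrix(ts)


def adjacency_from_connectivity(conn: np.ndarray, cfg: PipelineConfig):
    return connectivity.proportional_threshold(conn, density=cfg.density,
                                               mode=cfg.rank_mode)


def bc_delta_from_sessions(conn1: np.ndarray, conn2: np.ndarray,
                           cfg: PipelineConfig, node_ids=None,
                           label: str = "") -> longitudinal.DeltaMetricVector:
    """Betweenness change between two connectivity matrices."""
    bcs = []
    for conn in (conn1, conn2):
        adj = adjacency_from_connectivity(conn, cfg)
        spd = metrics.shortest_paths(adj.values)
        bc = metrics.betweenness(spd)
        bc.node_ids = np.asarray(node_ids) if node_ids is not None else None
        bcs.append(bc)
    return longitudinal.delta_metric(bcs[0], bcs[1], label=label)


def _resolve_mapping(node_table, cfg: PipelineConfig, lesion_side: str,
                     cache: dict):
    """Per-lesion-side anatomical attribution (flipped when requested)."""
    flip = cfg.flip_left_lesions and lesion_side == "Left"
    key = "flipped" if flip else "plain"
    if key not in cache:
        nt = atlas.flip_lesion_to_right(node_table, "Left") if flip else node_table
        regions = cfg.region_table if cfg.region_table is not None \
            else atlas.load_region_table()
        mapping = atlas.assign_nodes_to_regions(nt, regions,
                                                max_distance=cfg.max_distance)
        spec = cfg.roi_spec if cfg.roi_spec is not None else atlas.load_roi_spec()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = atlas.roi_node_sets(mapping, spec)
        cache[key] = (mapping, rois)
    return cache[key]


def analyze_cohort(cohort: SyntheticCohort, cfg: PipelineConfig = None) -> CohortResults:
    """Run both analysis paths over an in-memory cohort."""
    cfg = cfg or PipelineConfig()
    log: dict = {"stages": []}

    # -- scrubbing-based exclusion -----------------------------------------
    included, excluded = [], []
    for sub in cohort.subjects:
        decisions = [scrub_check(c, limit=cfg.scrub_limit) for c in sub.scrub]
        (included if all(d == INCLUDE for d in decisions) else excluded).append(sub)
    log["excluded_subjects"] = [s.subject_id for s in excluded]
    log["stages"].append({"stage": "scrub", "included": len(included),
                          "excluded": len(excluded)})
    if not included:
        raise RuntimeError("scrubbing excluded every subject")

    # -- per-subject connectivity ------------------------------------------
    conns: dict = {}
    for sub in included:
        for ts in (sub.ts1, sub.ts2):
            conns[(sub.subject_id, ts.session)] = subject_connectivity(ts, cfg)
    node_ids = cohort.node_table["node_id"].to_numpy()
    log["stages"].append({"stage": "connectivity", "matrices": len(conns)})

    map_cache: dict = {}
    plain_mapping, _ = _resolve_mapping(cohort.node_table, cfg, "Right", map_cache)
    log["unmapped_nodes"] = int((~plain_mapping["mapped"]).sum())

    # -- group path ---------------------------------------------------------
    group_results: dict = {}
    for group in sorted({s.group for s in included}):
        members = [s for s in included if s.group == group]
        session_metrics: dict = {}
        adjacency_info: dict = {}
        for ses in (1, 2):
            gavg = connectivity.group_average(
                [conns[(s.subject_id, ses)] for s in members],
                fisher=cfg.fisher_average)
            adj = adjacency_from_connectivity(gavg, cfg)
            adjacency_info[ses] = {"n_edges": adj.n_edges,
                                   "density": adj.density,
                                   "ties_at_cutoff": adj.ties_at_cutoff}
            session_metrics[ses] = metrics.all_metrics(
                adj.values, cpl_policy=cfg.cpl_policy, node_ids=node_ids)
        deltas, shown, summaries = {}, {}, {}
        for name in metrics.METRIC_NAMES:
            dm = longitudinal.delta_metric(session_metrics[1][name],
                                           session_metrics[2][name],
                                           label=group)
            mask = longitudinal.display_filter(dm)
            deltas[name] = dm
            shown[name] = mask
            summaries[name] = longitudinal.hemisphere_split(
                dm, plain_mapping, mask, cohort.node_table)
        group_results[group] = GroupResult(
            group=group, n_subjects=len(members),
            session_metrics=session_metrics, deltas=deltas, shown=shown,
            summaries=summaries, adjacency_info=adjacency_info)
        log["stages"].append({
            "stage": f"group-average:{group}", "n_subjects": len(members),
            "undefined_delta_counts": {m: int(deltas[m].undefined.sum())
                                       for m in metrics.METRIC_NAMES}})

    # -- individual path (betweenness vs motor recovery) --------------------
    panel_rows = []
    scores = {}
    bc_deltas: dict = {}
    motor_subs = [s for s in included if s.group == MOTOR]
    for sub in included:
        dbc = bc_delta_from_sessions(conns[(sub.subject_id, 1)],
                                     conns[(sub.subject_id, 2)],
                                     cfg, node_ids=node_ids,
                                     label=sub.subject_id)
        bc_deltas[sub.subject_id] = dbc
        if sub.group != MOTOR:
            continue
        try:
            scores[sub.subject_id] = clinical.delta_uefm(
                sub.clinical.get("uefm_t1"), sub.clinical.get("uefm_t2"))
        except ValueError:
            scores[sub.subject_id] = float("nan")
        _, rois = _resolve_mapping(cohort.node_table, cfg,
                                   sub.clinical.get("lesion_side", "Right"),
                                   map_cache)
        for (roi, side), nodes in sorted(rois.items()):
            hemi = "IL" if side == "Right" else "CL"
            panel_rows.append({
                "subject_id": sub.subject_id, "roi": roi, "hemisphere": hemi,
                "mean_dbc": clinical.roi_mean_delta_bc(dbc, nodes)})
    panel_means = pd.DataFrame(panel_rows,
                               columns=["subject_id", "roi", "hemisphere",
                                        "mean_dbc"])
    if len(panel_means) and len(scores) >= 3:
        fig5_results, fig5_scatter = clinical.run_fig5_analysis(
            panel_means, pd.Series(scores), alpha=cfg.alpha,
            method=cfg.method, correction=cfg.correction)
    else:
        fig5_results, fig5_scatter = [], pd.DataFrame()
    log["stages"].append({"stage": "fig5", "n_motor": len(motor_subs),
                          "n_panels": len(fig5_results)})

    return CohortResults(config=cfg, included=[s.subject_id for s in included],
                         excluded=[s.subject_id for s in excluded],
                         group_results=group_results,
                         fig5_results=fig5_results, fig5_scatter=fig5_scatter,
                         panel_means=panel_means,
                         subject_bc_delta=bc_deltas, connectivities=conns,
                         log=log)


# ---------------------------------------------------------------------------
# results-tree serialization (deterministic: fixed float formats, no clocks)

_FLOAT_FMT = "%.10g"


def _metrics_frame(subject_id, session, metric_dict) -> pd.DataFrame:
    rows = []
    for name in metrics.METRIC_NAMES:
        mv = metric_dict[name]
        ids = (mv.node_ids if mv.node_ids is not None
               else np.arange(1, mv.n + 1))
        for nid, val, und in zip(ids, mv.values, mv.undefined):
            rows.append({"subject_id": subject_id, "session": session,
                         "node_id": int(nid), "metric": name,
                         "value": val, "defined": not bool(und)})
    return pd.DataFrame(rows)


def write_results(results: CohortResults, cohort: SyntheticCohort, outdir) -> None:
    """Persist every stage's output as plain CSV/JSON under ``outdir``."""
    import json
    from pathlib import Path

    out = Path(outdir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    (out / "groups").mkdir(exist_ok=True)
    cfg = results.config
    node_ids = cohort.node_table["node_id"].to_numpy()

    # per-subject adjacency + all four metrics per session
    subjects = {s.subject_id: s for s in cohort.subjects}
    for sid in results.included:
        for ses in (1, 2):
            conn = results.connectivities[(sid, ses)]
            adj = adjacency_from_connectivity(conn, cfg)
            connectivity.write_edge_list(
                adj, out / "subjects" / f"{sid}_ses{ses}_edges.csv",
                node_ids=node_ids)
            md = metrics.all_metrics(adj.values, cpl_policy=cfg.cpl_policy,
                                     node_ids=node_ids)
            _metrics_frame(sid, ses, md).to_csv(
                out / "subjects" / f"{sid}_ses{ses}_metrics.csv",
                index=False, float_format=_FLOAT_FMT)
        dbc = results.subject_bc_delta[sid]
        longitudinal.delta_to_frame(dbc, longitudinal.display_filter(dbc)).to_csv(
            out / "subjects" / f"{sid}_bc_delta.csv",
            index=False, float_format=_FLOAT_FMT)

    # group path: average-graph metrics, change maps and region summaries
    for group, gr in sorted(results.group_results.items()):
        for ses in (1, 2):
            _metrics_frame(group, ses, gr.session_metrics[ses]).to_csv(
                out / "groups" / f"{group}_ses{ses}_metrics.csv",
                index=False, float_format=_FLOAT_FMT)
        for name in metrics.METRIC_NAMES:
            longitudinal.delta_to_frame(gr.deltas[name], gr.shown[name]).to_csv(
                out / "groups" / f"{group}_{name}_delta.csv",
                index=False, float_format=_FLOAT_FMT)
            for hemi in ("IL", "CL"):
                gr.summaries[name][hemi].to_csv(
                    out / "groups" / f"{group}_{name}_regions_{hemi}.csv",
                    index=False, float_format=_FLOAT_FMT)

    clinical.results_to_frame(results.fig5_results).to_csv(
        out / "correlations.csv", index=False, float_format=_FLOAT_FMT)
    if len(results.fig5_scatter):
        results.fig5_scatter.to_csv(out / "fig5_scatter.csv", index=False,
                                    float_format=_FLOAT_FMT)
    results.panel_means.to_csv(out / "panel_means.csv", index=False,
                               float_format=_FLOAT_FMT)

    log = dict(results.log)
    log["included"] = results.included
    log["excluded"] = results.excluded
    log["config"] = {
        "density": cfg.density, "rank_mode": cfg.rank_mode,
        "cpl_policy": cfg.cpl_policy, "alpha": cfg.alpha,
        "correction": cfg.correction, "method": cfg.method,
        "do_prewhiten": cfg.do_prewhiten, "max_order": cfg.max_order,
        "max_distance": cfg.max_distance, "scrub_limit": cfg.scrub_limit,
        "fisher_average": cfg.fisher_average,
        "flip_left_lesions": cfg.flip_left_lesions,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
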