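"""Synthetic two-session cohorts with known ground truth.

Generates per-subject node time series from a block latent-factor model
(one factor per community plus a global factor) with AR(1) temporal
structure, so Pearson matrices downstream show realistic modular
correlation. Session 2 re-draws the series after increasing the loadings of
a set of *target* nodes on the other communities' factors — turning them
into inter-community bridges, which is what betweenness centrality rewards.
For motor-group subjects the per-subject bridge-shift magnitude ``delta_s``
drives a simulated upper-extremity motor-score recovery, with a coupling
knob between 0 (decoupled) and 1 (deterministic).

Everything is deterministic given the master seed: per-subject generators
are seeded by a fixed offset scheme.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import atlas
from .clinical import CONTROL, MOTOR, UEFM_MAX
from .connectivity import TimeSeriesMatrix

_SEED_STRIDE = 7919  # fixed per-subject seed offset (prime)
_BURN_IN = 50

TOY_FAMILIES = ("complete", "star", "path", "ring", "empty")

DEFAULT_TARGET_ABBREVS = ("PrCG", "PoCG")  # left-hemisphere sensorimotor
PRIORITY_ABBREVS = ("PrCG", "PoCG", "MlFG", "SFG", "MFG")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Cohort design and generative parameters (defaults mirror the study
    design: 264 nodes, 180 time points at TR 2 s, 6 + 7 subjects)."""

    n_nodes: int = 264
    n_timepoints: int = 180
    tr: float = 2.0                      # seconds, metadata only
    n_motor: int = 6
    n_control: int = 7
    n_modules: int = 10
    module_partition: np.ndarray = None  # 0-based community per node
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0
    global_loading: float = 0.4
    loading_range: tuple = (0.6, 1.3)    # deterministic per-node spread
    background_bridge: tuple = (0.15, 0.5)  # per-node cross-community loading range
    target_nodes: tuple = None           # 1-based node ids; None = resolve default
    baseline_bridge: float = 1.0         # target loading on base bridge modules
    n_base_bridge: int = 3               # modules bridged in both sessions
    effect_strength: float = 0.25
    effect_spread: float = 0.9           # delta_s multiplier in [1-s, 1+s]
    delta_assignment: str = "stratified"  # "stratified" | "random"
    behavior_coupling: float = 0.7
    recovery_gain: float = 8.0           # score points per unit of delta_s
    recovery_noise_sd: float = 2.0
    uefm_baseline_range: tuple = (50, 66)
    lesion_side_mode: str = "random"     # "random" | "right"
    scrub_range: tuple = (0, 10)         # censored volumes drawn uniformly
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ConfigurationError("n_nodes must be >= 3")
        if self.n_timepoints < 10:
            raise ConfigurationError("n_timepoints must be >= 10")
        if self.n_motor < 0 or self.n_control < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.n_motor + self.n_control < 2:
            raise ConfigurationError("need at least 2 subjects in total")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ConfigurationError("ar_coefficient must be strictly inside (-1, 1)")
        if self.effect_strength < 0:
            raise ConfigurationError("effect_strength must be >= 0")
        if not 0.0 <= self.behavior_coupling <= 1.0:
            raise ConfigurationError("behavior_coupling must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ConfigurationError("n_modules must be in [1, n_nodes]")
        lo, hi = self.uefm_baseline_range
        if not (0 <= lo <= hi <= UEFM_MAX):
            raise ConfigurationError("uefm_baseline_range outside the 0-66 scale")
        if self.lesion_side_mode not in ("random", "right"):
            raise ConfigurationError("lesion_side_mode must be 'random' or 'right'")
        if self.delta_assignment not in ("stratified", "random"):
            raise ConfigurationError("delta_assignment must be 'stratified' or 'random'")
        if not 0.0 <= self.effect_spread < 1.0:
            raise ConfigurationError("effect_spread must be in [0, 1)")
        if self.baseline_bridge < 0 or self.n_base_bridge < 0:
            raise ConfigurationError("baseline bridge parameters must be >= 0")
        if self.module_partition is not None:
            part = np.asarray(self.module_partition)
            if part.size != self.n_nodes:
                raise ConfigurationError("module_partition length must equal n_nodes")
            self.module_partition = part
        if self.target_nodes is not None:
            targets = tuple(int(t) for t in self.target_nodes)
            if any(t < 1 or t > self.n_nodes for t in targets):
                raise ConfigurationError("target_nodes outside 1..n_nodes")
            self.target_nodes = targets

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["module_partition"] is not None:
            d["module_partition"] = [int(v) for v in d["module_partition"]]
        if d["target_nodes"] is not None:
            d["target_nodes"] = list(d["target_nodes"])
        d["uefm_baseline_range"] = list(d["uefm_baseline_range"])
        d["scrub_range"] = list(d["scrub_range"])
        d["loading_range"] = list(d["loading_range"])
        return d


@dataclass
class SubjectSim:
    """One simulated subject: two sessions plus clinical and ground truth."""

    subject_id: str
    group: str
    ts1: TimeSeriesMatrix
    ts2: TimeSeriesMatrix
    clinical: dict
    truth: dict
    scrub: tuple = (0, 0)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    node_table: pd.DataFrame
    subjects: list
    clinical: pd.DataFrame
    truth: pd.DataFrame
    target_nodes: tuple = ()

    @property
    def motor_subjects(self):
        return [s for s in self.subjects if s.group == MOTOR]


# ---------------------------------------------------------------------------
# node geometry

def make_node_table(n_nodes: int, region_table: pd.DataFrame = None,
                    priority_abbrevs=PRIORITY_ABBREVS) -> pd.DataFrame:
    """Synthetic node coordinates exercising the attribution machinery.

    Nodes are placed on the region table's coordinates first (priority
    regions, then the rest in table order) and any remainder on a symmetric
    +/-x lattice far laterally, so hemisphere flipping and region
    attribution both have work to do. Extra columns ``abbreviation`` and
    ``side`` record provenance (blank for lattice nodes).
    """
    if n_nodes < 1:
        raise ConfigurationError("n_nodes must be positive")
    if region_table is None:
        region_table = atlas.load_region_table()
    reg = region_table.dropna(subset=["x", "y", "z"]).reset_index(drop=True)
    prio = reg[reg["abbreviation"].isin(priority_abbrevs)]
    rest = reg[~reg["abbreviation"].isin(priority_abbrevs)]
    ordered = pd.concat([prio, rest]).reset_index(drop=True)
    rows = []
    for _, r in ordered.head(n_nodes).iterrows():
        rows.append((r["x"], r["y"], r["z"], r["abbreviation"], r["side"]))
    m = 0
    while len(rows) < n_nodes:
        y = -90.0 + 20.0 * (m % 10)
        z = -60.0 + 20.0 * ((m // 10) % 7)
        x = 78.0 + 12.0 * (m // 70)
        rows.append((x, y, z, "", ""))
        if len(rows) < n_nodes:
            rows.append((-x, y, z, "", ""))
        m += 1
    df = pd.DataFrame(rows[:n_nodes], columns=["x", "y", "z", "abbreviation", "side"])
    df.insert(0, "node_id", np.arange(1, n_nodes + 1))
    return df


def default_target_nodes(node_table: pd.DataFrame,
                         abbrevs=DEFAULT_TARGET_ABBREVS,
                         side: str = "Left") -> tuple:
    """Node ids of the left (contralesional, once lesions sit right)
    sensorimotor coordinates — the default site of the planted hub shift."""
    if "abbreviation" not in node_table.columns:
        raise ConfigurationError(
            "node table lacks provenance columns; pass target_nodes explicitly")
    sel = node_table["abbreviation"].isin(abbrevs) & (node_table["side"] == side)
    ids = tuple(int(v) for v in node_table.loc[sel, "node_id"])
    if not ids:
        raise ConfigurationError("no default target nodes found in node table")
    return ids


def _default_partition(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal communities over node index order."""
    return np.minimum(np.arange(n_nodes) * n_modules // n_nodes, n_modules - 1)


# ---------------------------------------------------------------------------
# time-series generation

def _ar1(rng, n_rows: int, n_cols: int, a: float) -> np.ndarray:
    """Stationary unit-variance AR(1) columns (burn-in discarded)."""
    e = rng.standard_normal((n_rows + _BURN_IN, n_cols))
    x = signal.lfilter([1.0], [1.0, -a], e, axis=0) * np.sqrt(1.0 - a * a)
    return x[_BURN_IN:]


def _loadings(config: SimulationConfig, partition: np.ndarray,
              targets0: np.ndarray, delta: float) -> np.ndarray:
    """Factor-loading matrix (nodes x [module factors + global factor]).

    Every node loads on its own community factor with a deterministic
    per-node weight spread over ``loading_range`` (heterogeneity keeps the
    proportional-threshold cutoff away from large blocks of tied
    correlations, so the thresholded backbone is stable across draws).
    Target nodes additionally bridge: a constant ``baseline_bridge`` loading
    on the ``n_base_bridge`` communities after their own (both sessions;
    anchors their betweenness at a stable level), plus ``delta`` times a
    deterministic per-(target, community) coefficient in [0.5, 1.5) on the
    remaining communities — so bridge edges switch on progressively as the
    shift grows.
    """
    k = config.n_modules
    n = config.n_nodes
    idx = np.arange(n)
    lo, hi = config.loading_range
    lam = lo + (hi - lo) * ((idx * 37) % 64) / 64.0
    w = np.zeros((n, k + 1))
    w[idx, partition] = lam
    w[:, k] = config.global_loading
    if k > 1:
        # every node integrates weakly with one fixed other community, so
        # baseline betweenness sits above the granularity floor everywhere
        # (keeps the relative-change ratio well conditioned off-target)
        blo, bhi = config.background_bridge
        beta = blo + (bhi - blo) * ((idx * 13) % 32) / 32.0
        second = (partition + 1 + (idx % (k - 1))) % k
        w[idx, second] += beta
    n_base = min(config.n_base_bridge, k - 1)
    for i in targets0:
        own = partition[i]
        base = [(own + j) % k for j in range(1, n_base + 1)]
        w[i, base] += config.baseline_bridge
        if delta != 0.0:
            shift = [m for m in range(k) if m != own and m not in base]
            if not shift:          # few communities: shift rides on the base set
                shift = base
            for m in shift:
                c = 0.5 + ((i * 11 + m * 29) % 16) / 16.0
                w[i, m] += delta * c
    return w


def _session_series(rng, config: SimulationConfig, w: np.ndarray) -> np.ndarray:
    t = config.n_timepoints
    factors = _ar1(rng, t, w.shape[1], config.ar_coefficient)
    noise = _ar1(rng, t, config.n_nodes, config.ar_coefficient)
    return factors @ w.T + config.noise_sd * noise


# ---------------------------------------------------------------------------
# subjects and cohorts

def simulate_subject(config: SimulationConfig, group: str, subject_seed: int,
                     node_table: pd.DataFrame = None,
                     subject_id: str = None,
                     dose_rank: tuple = None) -> SubjectSim:
    """Draw one subject's two sessions, clinical record and ground truth.

    ``dose_rank=(rank, total)`` places a motor subject's shift magnitude on
    a stratified grid over the configured spread (used by
    :func:`simulate_cohort` when ``delta_assignment="stratified"``);
    without it the multiplier is drawn uniformly.
    """
    if group not in (MOTOR, CONTROL):
        raise ConfigurationError(f"group must be '{MOTOR}' or '{CONTROL}'")
    if node_table is None:
        node_table = make_node_table(config.n_nodes)
    if len(node_table) != config.n_nodes:
        raise ConfigurationError("node table size does not match n_nodes")
    partition = (config.module_partition if config.module_partition is not None
                 else _default_partition(config.n_nodes, config.n_modules))
    targets = (config.target_nodes if config.target_nodes is not None
               else default_target_nodes(node_table))
    targets0 = np.asarray(targets, dtype=int) - 1
    if targets0.size and (targets0.min() < 0 or targets0.max() >= config.n_nodes):
        raise ConfigurationError("target_nodes outside 1..n_nodes")
    sid = subject_id or ("M" if group == MOTOR else "C")
    rng = np.random.default_rng(subject_seed)

    if config.lesion_side_mode == "right":
        lesion_side = "Right"
    else:
        lesion_side = str(rng.choice(["Right", "Left"]))

    if group == MOTOR:
        spread = config.effect_spread
        u = float(rng.uniform(1.0 - spread, 1.0 + spread))
        if config.delta_assignment == "stratified" and dose_rank is not None:
            rank, total = dose_rank
            u = (1.0 - spread) + 2.0 * spread * (rank + 0.5) / max(total, 1)
        delta_s = config.effect_strength * u
    else:
        delta_s = 0.0
    eps = float(rng.normal(0.0, config.recovery_noise_sd))

    clinical = {"subject_id": sid, "group": group, "lesion_side": lesion_side}
    if group == MOTOR:
        rankin1 = int(rng.integers(1, 3))            # 1 or 2
        barthel1 = int(rng.choice([85, 90, 95]))     # < 100
        nihss = int(rng.integers(0, 9))
        lo, hi = config.uefm_baseline_range
        uefm1 = int(rng.integers(lo, hi + 1))
        lefm1 = int(rng.integers(30, 35))
        recovery = (config.behavior_coupling * config.recovery_gain * delta_s
                    + (1.0 - config.behavior_coupling) * eps)
        uefm2 = int(np.clip(round(uefm1 + recovery), 0, UEFM_MAX))
        clinical.update(
            rankin_t1=rankin1, rankin_t2=max(0, rankin1 - int(rng.integers(0, 2))),
            barthel_t1=barthel1,
            barthel_t2=int(min(100, barthel1 + 5 * int(rng.integers(0, 3)))),
            nihss=nihss,
            uefm_t1=uefm1, uefm_t2=uefm2,
            lefm_t1=lefm1, lefm_t2=int(np.clip(lefm1 + int(rng.integers(0, 3)), 0, 34)),
        )
        truth_delta_uefm = float(uefm2 - uefm1)
    else:
        rankin1 = int(rng.integers(0, 2))            # 0 or 1
        clinical.update(
            rankin_t1=rankin1, rankin_t2=max(0, rankin1 - int(rng.integers(0, 2))),
            barthel_t1=100, barthel_t2=100,
            nihss=int(rng.integers(0, 3)),
            uefm_t1=np.nan, uefm_t2=np.nan, lefm_t1=np.nan, lefm_t2=np.nan,
        )
        truth_delta_uefm = float("nan")

    scrub = (int(rng.integers(config.scrub_range[0], config.scrub_range[1] + 1)),
             int(rng.integers(config.scrub_range[0], config.scrub_range[1] + 1)))

    w1 = _loadings(config, partition, targets0, 0.0)
    w2 = _loadings(config, partition, targets0, delta_s)
    node_ids = node_table["node_id"].to_numpy()
    data1 = _session_series(rng, config, w1)
    data2 = _session_series(rng, config, w2)
    ts1 = TimeSeriesMatrix(data1, subject_id=sid, session=1, node_ids=node_ids,
                           meta={"tr": config.tr})
    ts2 = TimeSeriesMatrix(data2, subject_id=sid, session=2, node_ids=node_ids,
                           meta={"tr": config.tr})
    truth = {"subject_id": sid, "group": group, "delta_s": delta_s,
             "delta_uefm": truth_delta_uefm}
    return SubjectSim(sid, group, ts1, ts2, clinical, truth, scrub=scrub)


def subject_seeds(config: SimulationConfig) -> list[int]:
    n = config.n_motor + config.n_control
    return [config.seed + _SEED_STRIDE * (i + 1) for i in range(n)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full two-group cohort, deterministic given ``config.seed``."""
    node_table = make_node_table(config.n_nodes)
    targets = (config.target_nodes if config.target_nodes is not None
               else default_target_nodes(node_table))
    seeds = subject_seeds(config)
    labels = ([(MOTOR, f"M{i + 1:02d}", (i, config.n_motor))
               for i in range(config.n_motor)]
              + [(CONTROL, f"C{i + 1:02d}", None)
                 for i in range(config.n_control)])
    subjects = [
        simulate_subject(config, group, seed, node_table=node_table,
                         subject_id=sid, dose_rank=rank)
        for (group, sid, rank), seed in zip(labels, seeds)
    ]
    clinical = pd.DataFrame([s.clinical for s in subjects])
    truth = pd.DataFrame([s.truth for s in subjects])
    return SyntheticCohort(config, node_table, subjects, clinical, truth,
                           target_nodes=tuple(targets))


# ---------------------------------------------------------------------------
# toy graphs

def make_toy_graph(name: str, n: int) -> np.ndarray:
    """Canonical binary undirected graphs for exercising the metrics."""
    if name not in TOY_FAMILIES:
        raise ValueError(f"unknown graph family {name!r}; choose from {TOY_FAMILIES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    a = np.zeros((n, n), dtype=np.int8)
    if name == "complete":
        a[:] = 1
        np.fill_diagonal(a, 0)
    elif name == "star":
        a[0, 1:] = 1
        a[1:, 0] = 1
    elif name == "path":
        idx = np.arange(n - 1)
        a[idx, idx + 1] = 1
        a[idx + 1, idx] = 1
    elif name == "ring":
        idx = np.arange(n)
        a[idx, (idx + 1) % n] = 1
        a[(idx + 1) % n, idx] = 1
        np.fill_diagonal(a, 0)  # ring on n<3 degenerates
        a = np.maximum(a, a.T)
    return a


# ---------------------------------------------------------------------------
# plain-text serialization

def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort as delimited text plus a checksum manifest.

    One TSV per subject-session (T rows x N columns, header of node ids),
    ``nodes.csv``, ``clinical.csv``, ``scrub.csv``, ``ground_truth.csv``
    and ``manifest.json``. Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    nodes = cohort.node_table[["node_id", "x", "y", "z"]]
    nodes.to_csv(out / "nodes.csv", index=False, float_format="%.10g")
    files.append("nodes.csv")
    cohort.clinical.to_csv(out / "clinical.csv", index=False, float_format="%.10g")
    files.append("clinical.csv")
    cohort.truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.10g")
    files.append("ground_truth.csv")

    scrub_rows = [{"subject_id": s.subject_id, "session": ses + 1,
                   "censored_volumes": s.scrub[ses]}
                  for s in cohort.subjects for ses in (0, 1)]
    pd.DataFrame(scrub_rows).to_csv(out / "scrub.csv", index=False)
    files.append("scrub.csv")

    header = "\t".join(str(n) for n in cohort.node_table["node_id"])
    for s in cohort.subjects:
        for ts in (s.ts1, s.ts2):
            name = f"{s.subject_id}_ses{ts.session}.tsv"
            np.savetxt(out / name, ts.data, fmt="%.8g", delimiter="\t",
                       header=header, comments="")
            files.append(name)

    manifest = {
        "config": cohort.config.to_dict(),
        "subject_seeds": subject_seeds(cohort.config),
        "target_nodes": list(cohort.target_nodes),
        "files": {name: _sha256(out / name) for name in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort(indir) -> SyntheticCohort:
    """Re-read a cohort written by :func:`write_cohort` (or hand-built files
    in the same layout) into memory. ``ground_truth.csv`` is optional;
    missing group labels are derived from the clinical scores."""
    from .clinical import assign_groups
    from .connectivity import load_timeseries

    indir = Path(indir)
    clin_path = indir / "clinical.csv"
    if not clin_path.exists():
        raise FileNotFoundError(f"no clinical.csv under {indir}")
    clinical_df = pd.read_csv(clin_path)
    if "group" not in clinical_df.columns:
        clinical_df["group"] = assign_groups(clinical_df)
    nodes_path = indir / "nodes.csv"
    node_table = (atlas.load_node_table(nodes_path) if nodes_path.exists() else None)
    scrub_path = indir / "scrub.csv"
    scrub = {}
    if scrub_path.exists():
        for _, row in pd.read_csv(scrub_path).iterrows():
            scrub.setdefault(row["subject_id"], {})[int(row["session"])] = \
                int(row["censored_volumes"])
    truth_path = indir / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()

    subjects = []
    for _, row in clinical_df.iterrows():
        sid = row["subject_id"]
        ts = {}
        for ses in (1, 2):
            path = indir / f"{sid}_ses{ses}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing time-series file {path}")
            ts[ses] = load_timeseries(path, subject_id=sid, session=ses)
        if ts[1].n_nodes != ts[2].n_nodes:
            raise ValueError(f"subject {sid}: sessions differ in node count")
        sc = scrub.get(sid, {1: 0, 2: 0})
        t = truth[truth["subject_id"] == sid] if len(truth) else pd.DataFrame()
        subjects.append(SubjectSim(
            sid, row["group"], ts[1], ts[2], row.to_dict(),
            t.iloc[0].to_dict() if len(t) else {},
            scrub=(sc.get(1, 0), sc.get(2, 0))))
    if not subjects:
        raise ValueError(f"no subjects found under {indir}")
    if node_table is None:
        n = subjects[0].ts1.n_nodes
        node_table = pd.DataFrame({"node_id": subjects[0].ts1.node_ids,
                                   "x": np.zeros(n), "y": np.zeros(n),
                                   "z": np.zeros(n)})
    return SyntheticCohort(None, node_table, subjects, clinical_df, truth)
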