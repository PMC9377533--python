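"""Node tables, hemisphere flipping and anatomical region attribution.

Nodes are points in MNI millimetre space (``node_id, x, y, z``). Regions are
named anatomical entries with one or more representative coordinates; a node
is attributed to the region owning the Euclidean-nearest coordinate, with a
cap distance beyond which the node stays unmapped.

The packaged region table ships with the distribution; external coordinate
lists (e.g. a full functional atlas) load through the same readers.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml

SIDES = ("Left", "Right")

DEFAULT_MAX_DISTANCE = 15.0  # mm; beyond this a node is left unattributed


def _packaged(name: str):
    return resources.files("fcgraph.data").joinpath(name)


def load_node_table(path) -> pd.DataFrame:
    """Read and validate a delimited node table with id and x/y/z columns.

    Row order is preserved as node index order. Raises ``ValueError`` with
    the offending row/id on duplicates or non-numeric coordinates.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["node_id", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"node table is missing columns {missing}")
    if len(df) == 0:
        raise ValueError("node table is empty")
    dup = df["node_id"][df["node_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate node id {dup.iloc[0]!r} in node table")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at row {bad[0] + 1}")
        df[col] = vals.astype(float)
    return df[required].reset_index(drop=True)


def load_region_table(path=None) -> pd.DataFrame:
    """Read a region coordinate table (defaults to the packaged one).

    Columns: ``region, abbreviation, side, x, y, z`` — one row per
    coordinate. Entries published without coordinates appear as rows with
    empty x/y/z and contribute no attribution targets.
    """
    src = path if path is not None else _packaged("aal_regions.csv")
    df = pd.read_csv(src)
    required = ["region", "abbreviation", "side", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table is missing columns {missing}")
    bad_side = set(df["side"].dropna()) - set(SIDES)
    if bad_side:
        raise ValueError(f"unknown side labels {sorted(bad_side)}")
    return df[required]


def flip_lesion_to_right(nodes: pd.DataFrame, lesion_side: str) -> pd.DataFrame:
    """Mirror node coordinates across the midsagittal plane when the lesion
    is on the left, so every subject's lesion sits in the right hemisphere.

    Negates x (y and z untouched) for ``lesion_side == "Left"``; identity
    for ``"Right"``. Applying the operation twice restores the input.
    """
    if lesion_side not in SIDES:
        raise ValueError(f"unknown lesion side {lesion_side!r}; expected one of {SIDES}")
    out = nodes.copy()
    if lesion_side == "Left":
        out["x"] = -out["x"]
        if "side" in out.columns:
            out["side"] = out["side"].map({"Left": "Right", "Right": "Left"}).fillna(out["side"])
    return out


def assign_nodes_to_regions(nodes: pd.DataFrame, regions: pd.DataFrame,
                            max_distance: float = DEFAULT_MAX_DISTANCE) -> pd.DataFrame:
    """Attribute each node to the anatomical region with the nearest
    coordinate (Euclidean, in mm).

    Nodes farther than ``max_distance`` from every region coordinate are
    flagged unmapped. Ties are broken by region-table row order. Returns a
    frame with columns ``node_id, region, abbreviation, side, distance,
    mapped`` in node order.
    """
    if len(nodes) == 0:
        raise ValueError("node table is empty")
    reg = regions.dropna(subset=["x", "y", "z"]).reset_index(drop=True)
    if len(reg) == 0:
        raise ValueError("region table has no coordinates")
    npts = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    rpts = reg[["x", "y", "z"]].to_numpy(dtype=float)
    d2 = ((npts[:, None, :] - rpts[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest row index) minimum: the tie rule
    best = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(nodes)), best])
    mapped = dist <= max_distance
    out = pd.DataFrame({
        "node_id": nodes["node_id"].to_numpy(),
        "region": np.where(mapped, reg["region"].to_numpy()[best], None),
        "abbreviation": np.where(mapped, reg["abbreviation"].to_numpy()[best], None),
        "side": np.where(mapped, reg["side"].to_numpy()[best], None),
        "distance": dist,
        "mapped": mapped,
    })
    return out


def load_roi_spec(path=None) -> dict[str, list[str]]:
    """ROI name -> list of region abbreviations (defaults packaged)."""
    if path is None:
        text = _packaged("roi_default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    if spec is None:
        return {}
    if not isinstance(spec, dict):
        raise ValueError("ROI spec must map ROI names to abbreviation lists")
    return {str(k): [str(a) for a in v] for k, v in spec.items()}


def roi_node_sets(node_region_map: pd.DataFrame,
                  roi_spec: dict[str, list[str]]) -> dict[tuple[str, str], set]:
    """Resolve ROI groupings to per-(ROI, side) node-id sets.

    An ROI naming abbreviations absent from the map yields an empty set
    with a warning rather than an error.
    """
    known = set(node_region_map.loc[node_region_map["mapped"], "abbreviation"])
    out: dict[tuple[str, str], set] = {}
    for roi, abbrevs in roi_spec.items():
        unknown = [a for a in abbrevs if a not in known]
        if unknown:
            warnings.warn(
                f"ROI {roi!r}: no mapped nodes for abbreviation(s) {unknown}",
                stacklevel=2)
        for side in SIDES:
            sel = (node_region_map["mapped"]
                   & node_region_map["abbreviation"].isin(abbrevs)
                   & (node_region_map["side"] == side))
            ids = set(node_region_map.loc[sel, "node_id"])
            if not ids:
                warnings.warn(f"ROI {roi!r} ({side}) resolves to an empty node set",
                              stacklevel=2)
            out[(roi, side)] = ids
    return out
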