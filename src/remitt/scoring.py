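"""T-cell spot detection and exhaustion scoring.

The exhaustion score of a T-cell-infiltrated spot is defined as the residual
of an ordinary least-squares regression of summed exhaustion-marker
expression on summed T-marker expression across T spots, shifted so the
minimum residual is 0.  The regression controls for the number of T cells in
a spot (more T cells, more marker transcript of both kinds); what remains is
how exhausted those T cells are.

For Visium HD, per-pixel scores are aggregated into spatially coherent nodes
by greedy region growing: a seed pixel absorbs its unassigned neighbors
within a fixed radius whose scores lie within a small tolerance.

Node tables are plain pandas DataFrames with columns
``node_id, x, y, z, t_marker_sum, umi_total, members`` — one row per analysis
unit (a spot on standard Visium, an aggregated pixel group on HD).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .st_io import GenePanels, STDataset, normalize_counts

logger = logging.getLogger(__name__)

NODE_COLUMNS = ["node_id", "x", "y", "z", "t_marker_sum", "umi_total", "members"]


def validate_node_table(nodes: pd.DataFrame) -> None:
    """Check the node-table invariants shared by all downstream stages."""
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise ValueError(f"node table missing columns {missing}")
    if nodes["node_id"].duplicated().any():
        raise ValueError("duplicate node ids")
    z = nodes["z"].to_numpy(float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite exhaustion scores")
    if len(nodes) and abs(z.min()) > 1e-9:
        raise ValueError("exhaustion scores must be shifted so min(z) == 0")
    members = [m for ms in nodes["members"] for m in ms]
    if len(members) != len(set(members)):
        raise ValueError("a spot belongs to more than one node")


def detect_t_spots(ds: STDataset, panels: GenePanels | None = None,
                   threshold: float = 0.0) -> np.ndarray:
    """Spot ids whose summed raw T-marker counts exceed ``threshold``.

    The default threshold of 0 calls any spot with at least one detected
    T-marker transcript as T-cell infiltrated.  Input order is preserved.
    """
    panels = panels or GenePanels()
    present = [g for g in panels.t_markers if g in set(ds.gene_names)]
    if not present:
        raise ValueError(
            f"none of the T markers {panels.t_markers} are in the dataset"
        )
    sums = ds.marker_counts(present)
    return ds.spot_ids[sums > threshold]


def exhaustion_score(ds: STDataset, t_spots, panels: GenePanels | None = None,
                     use_normalized: bool = True) -> pd.DataFrame:
    """One node per T spot with residual exhaustion score ``z`` (min 0).

    By default both marker sums are computed on per-spot TPM-normalized
    expression so the score is comparable across sequencing depths; set
    ``use_normalized=False`` to regress raw count sums.
    """
    panels = panels or GenePanels()
    sub = ds.subset_spots(list(t_spots))
    if sub.n_spots < 3:
        raise ValueError(f"need at least 3 T spots, got {sub.n_spots}")

    if use_normalized:
        mat = normalize_counts(sub)
        t_sum = mat[[g for g in panels.t_markers if g in mat.columns]].sum(axis=1)
        e_sum = mat[[g for g in panels.exhaustion_markers if g in mat.columns]].sum(axis=1)
        x = t_sum.to_numpy(float)
        y = e_sum.to_numpy(float)
        kept_ids = mat.index.to_numpy()
    else:
        x = sub.marker_counts(panels.t_markers).astype(float)
        y = sub.marker_counts(panels.exhaustion_markers).astype(float)
        kept_ids = sub.spot_ids

    if np.ptp(x) == 0:
        raise ValueError(
            "T-marker sums are constant across T spots; the exhaustion "
            "regression is undefined — review the T-spot threshold"
        )

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    logger.info("exhaustion regression: slope=%.4g intercept=%.4g R2=%.3f",
                slope, intercept, r2)
    z = resid - resid.min()

    order = {s: i for i, s in enumerate(sub.spot_ids)}
    idx = np.array([order[s] for s in kept_ids], dtype=int)
    nodes = pd.DataFrame({
        "node_id": kept_ids,
        "x": sub.xy[idx, 0],
        "y": sub.xy[idx, 1],
        "z": z,
        "t_marker_sum": x,
        "umi_total": sub.umi_total[idx],
        "members": [(s,) for s in kept_ids],
    })
    nodes.attrs["regression"] = {"slope": float(slope),
                                 "intercept": float(intercept),
                                 "r2": float(r2)}
    validate_node_table(nodes)
    return nodes


def hd_aggregate(pixel_nodes: pd.DataFrame, pitch_um: float,
                 radius_factor: float = 5.0,
                 tol: float | None = None) -> pd.DataFrame:
    """Region-grow HD pixels into nodes of similar exhaustion score.

    Seeds are visited in descending ``t_marker_sum`` (ties by node id, which
    makes the greedy partition deterministic).  Each seed absorbs every
    still-unassigned pixel within ``radius_factor * pitch_um`` whose score
    differs from the seed's by at most ``tol``; the node's score is the
    member mean and its coordinates the member centroid.  Every pixel ends up
    in exactly one node.

    ``tol`` defaults to 5% of the observed score range.
    """
    if radius_factor <= 0:
        raise ValueError("radius_factor must be positive")
    z = pixel_nodes["z"].to_numpy(float)
    if tol is None:
        tol = 0.05 * (np.ptp(z) if len(z) else 0.0)
    if tol < 0:
        raise ValueError("tol must be non-negative")

    xy = pixel_nodes[["x", "y"]].to_numpy(float)
    ids = pixel_nodes["node_id"].to_numpy()
    tree = cKDTree(xy)
    radius = radius_factor * pitch_um

    seed_order = sorted(
        range(len(pixel_nodes)),
        key=lambda i: (-pixel_nodes["t_marker_sum"].iat[i], ids[i]),
    )
    assigned = np.zeros(len(pixel_nodes), dtype=bool)
    groups = []
    for seed in seed_order:
        if assigned[seed]:
            continue
        neigh = tree.query_ball_point(xy[seed], radius)
        members = [j for j in sorted(neigh)
                   if not assigned[j] and abs(z[j] - z[seed]) <= tol]
        if seed not in members:
            members.append(seed)
        for j in members:
            assigned[j] = True
        groups.append((seed, members))

    rows = []
    for k, (seed, members) in enumerate(groups):
        m = np.array(members, dtype=int)
        member_spots = tuple(s for j in m for s in pixel_nodes["members"].iat[j])
        rows.append({
            "node_id": f"node_{k:05d}",
            "x": xy[m, 0].mean(),
            "y": xy[m, 1].mean(),
            "z": z[m].mean(),
            "t_marker_sum": pixel_nodes["t_marker_sum"].to_numpy(float)[m].sum(),
            "umi_total": pixel_nodes["umi_total"].to_numpy(float)[m].sum(),
            "members": member_spots,
            "seed": ids[seed],
        })
    nodes = pd.DataFrame(rows)
    nodes["z"] -= nodes["z"].min()
    validate_node_table(nodes)
    return nodes
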