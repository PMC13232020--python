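"""Matched control trails and the empirical permutation null.

Every systematic claim about a migration trail is judged against *matched
control trails*: random self-avoiding walks over T spots of the same
expression cluster, with the same length, the same adjacency constraint and
the same minimum start-to-end span (0.5 mm) as the real trail.  One control
per real trail forms a control set; thousands of sets (5,000 in a full run)
form the empirical null distribution for any statistic of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .trailfinder import MIN_SPAN_UM, Trail

logger = logging.getLogger(__name__)

N_CLUSTERS = 6
N_PCS = 30
N_CONTROL_SETS = 5000


@dataclass
class ControlSet:
    """One matched control trail per real trail."""

    set_id: int
    controls: list  # node-id tuples, aligned with the trail list


def cluster_spots(mat: pd.DataFrame, k: int = N_CLUSTERS, n_pcs: int = N_PCS,
                  rng_seed: int = 0) -> pd.Series:
    """PCA + k-means cluster labels for every spot.

    ``mat`` is a spots x variable-genes normalized matrix; it is log1p
    transformed before PCA.  Deterministic given ``rng_seed``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(mat) < k:
        raise ValueError(f"cannot form {k} clusters from {len(mat)} spots")
    x = np.log1p(mat.to_numpy(float))
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs >= 1:
        x = PCA(n_components=n_pcs, random_state=rng_seed).fit_transform(x)
    labels = KMeans(n_clusters=k, n_init=10, random_state=rng_seed).fit_predict(x)
    return pd.Series(labels, index=mat.index, name="cluster")


def trail_cluster(trail: Trail, labels: pd.Series) -> int:
    """Majority cluster of a trail's member spots (ties to the smaller label)."""
    present = [n for n in trail.nodes if n in labels.index]
    if not present:
        raise ValueError("no trail spot has a cluster label")
    counts = labels.loc[present].value_counts()
    top = counts.max()
    return int(min(c for c in counts.index if counts[c] == top))


def validate_control(control, trail: Trail, labels: pd.Series,
                     adjacency: dict, nodes: pd.DataFrame,
                     min_span: float = MIN_SPAN_UM) -> None:
    """Checker for the five matching constraints of a control trail."""
    if len(control) != len(trail):
        raise ValueError("control length differs from its matched trail")
    if tuple(control) in (tuple(trail.nodes), tuple(reversed(trail.nodes))):
        raise ValueError("control equals the matched trail's own path")
    cluster = trail_cluster(trail, labels)
    if any(labels.get(n, -1) != cluster for n in control):
        raise ValueError("control leaves the matched trail's cluster")
    for u, v in zip(control[:-1], control[1:]):
        if v not in adjacency.get(u, ()):
            raise ValueError(f"control nodes {u} and {v} are not adjacent")
    pos = nodes.set_index("node_id")
    span = float(np.hypot(pos.at[control[0], "x"] - pos.at[control[-1], "x"],
                          pos.at[control[0], "y"] - pos.at[control[-1], "y"]))
    if span < min_span:
        raise ValueError(f"control span {span:.0f} um below {min_span}")
    if len(set(control)) != len(control):
        raise ValueError("control revisits a node")


def sample_control_trail(trail: Trail, labels: pd.Series, adjacency: dict,
                         nodes: pd.DataFrame, rng: np.random.Generator,
                         min_span: float = MIN_SPAN_UM,
                         max_attempts: int = 2000):
    """One matched control: a cluster-confined self-avoiding walk.

    Starts from a uniformly drawn T spot of the trail's majority cluster and
    walks uniformly among unvisited same-cluster neighbors until it reaches
    the trail's length; accepted when the start-end span is at least
    ``min_span`` and the sequence differs from the trail itself.  Returns
    ``None`` if ``max_attempts`` walks all fail.
    """
    cluster = trail_cluster(trail, labels)
    pool = [n for n in labels.index[labels == cluster] if n in adjacency]
    if len(pool) < len(trail):
        return None
    pos = nodes.set_index("node_id")
    length = len(trail)
    # the trail's own path, in either orientation, is not a valid control
    banned = {tuple(trail.nodes), tuple(reversed(trail.nodes))}
    for _ in range(max_attempts):
        start = pool[rng.integers(len(pool))]
        path = [start]
        visited = {start}
        while len(path) < length:
            options = [n for n in adjacency.get(path[-1], ())
                       if n not in visited and labels.get(n, -1) == cluster]
            if not options:
                break
            nxt = options[rng.integers(len(options))]
            path.append(nxt)
            visited.add(nxt)
        if len(path) != length or tuple(path) in banned:
            continue
        span = float(np.hypot(pos.at[path[0], "x"] - pos.at[path[-1], "x"],
                              pos.at[path[0], "y"] - pos.at[path[-1], "y"]))
        if span < min_span:
            continue
        return tuple(path)
    return None


def generate_control_sets(trails, labels: pd.Series, adjacency: dict,
                          nodes: pd.DataFrame, n_sets: int = N_CONTROL_SETS,
                          rng_seed: int = 0,
                          min_span: float = MIN_SPAN_UM,
                          max_attempts: int = 2000,
                          max_reseeds: int = 5) -> list:
    """``n_sets`` control sets, one control per real trail in each.

    A failed (trail, set) draw is retried with a fresh child seed; persistent
    failure raises a diagnostic error naming the trail (typically the trail's
    cluster is too small to host any other admissible walk).
    """
    if not trails:
        raise ValueError("no trails to match controls to")
    root = np.random.SeedSequence(rng_seed)
    sets = []
    for set_id, child in enumerate(root.spawn(n_sets)):
        rng = np.random.default_rng(child)
        controls = []
        for t_idx, trail in enumerate(trails):
            control = sample_control_trail(trail, labels, adjacency, nodes,
                                           rng, min_span=min_span,
                                           max_attempts=max_attempts)
            reseed = 0
            while control is None and reseed < max_reseeds:
                reseed += 1
                fresh = np.random.default_rng(child.spawn(1)[0])
                control = sample_control_trail(trail, labels, adjacency,
                                               nodes, fresh,
                                               min_span=min_span,
                                               max_attempts=max_attempts)
            if control is None:
                raise RuntimeError(
                    f"could not draw a matched control for trail "
                    f"{trail.start}->{trail.end} (index {t_idx}) after "
                    f"{max_reseeds} reseeds; its cluster may be too sparse"
                )
            controls.append(control)
        sets.append(ControlSet(set_id=set_id, controls=controls))
    return sets


def empirical_p(observed: float, null_values, convention: str = "plain") -> float:
    """Two-sided empirical p of ``observed`` against a permutation null.

    ``plain`` (default): ``p = min(1, 2 * min(#null >= obs, #null <= obs) / n)``,
    which can reach exactly 0.  ``add_one`` applies the (count+1)/(n+1)
    correction.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    n = null_values.size
    if n == 0:
        raise ValueError("empty null distribution")
    ge = int(np.sum(null_values >= observed))
    le = int(np.sum(null_values <= observed))
    if convention == "plain":
        return min(1.0, 2.0 * min(ge, le) / n)
    if convention == "add_one":
        return min(1.0, 2.0 * (min(ge, le) + 1) / (n + 1))
    raise ValueError(f"unknown convention {convention!r}")
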