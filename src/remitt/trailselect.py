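"""Trail selection by T-cell stage-gene coherence against alternative routes.

A stream of T cells moving along a physical corridor should show more
coherent stage-marker expression from spot to spot than an arbitrary path
between the same endpoints.  For every candidate trail we therefore sample
5-15 *alternative routes* between its endpoints (same adjacency, length and
span constraints, but no requirement of increasing exhaustion) and keep the
candidate only if its mean pairwise stage-gene correlation (a) beats every
one of its own alternatives and (b) exceeds the 85th percentile of all
alternative routes pooled across candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trailfinder import MIN_NODES, MIN_SPAN_UM, Trail

logger = logging.getLogger(__name__)

K_MIN_ROUTES = 5
K_MAX_ROUTES = 15
SELECT_PERCENTILE = 85.0


def select_stage_genes(mat: pd.DataFrame, candidates,
                       t_marker_sum: pd.Series,
                       alpha: float = 0.05,
                       method: str = "pearson",
                       min_genes: int = 3) -> list:
    """Stage-gene candidates positively correlated with T-marker level.

    Keeps candidate genes whose correlation with ``t_marker_sum`` across T
    spots is positive with a two-sided p below ``alpha``.  If fewer than
    ``min_genes`` pass (degenerate slides), falls back to the top
    ``min_genes`` candidates by correlation so the downstream coherence
    score stays defined.
    """
    candidates = [g for g in candidates if g in mat.columns]
    if not candidates:
        raise ValueError("no stage-gene candidates present in the matrix")
    if len(mat) < 10:
        raise ValueError("need at least 10 T spots for stage-gene selection")
    t = t_marker_sum.loc[mat.index].to_numpy(float)

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    results = []
    for g in candidates:
        v = mat[g].to_numpy(float)
        if np.ptp(v) == 0 or np.ptp(t) == 0:
            results.append((g, 0.0, 1.0))
            continue
        r, p = corr_fn(v, t)
        results.append((g, float(r), float(p)))

    selected = [g for g, r, p in results if r > 0 and p < alpha]
    if len(selected) < min_genes:
        logger.warning(
            "only %d stage genes passed the correlation filter; "
            "falling back to the top %d by correlation", len(selected), min_genes,
        )
        selected = [g for g, _, _ in
                    sorted(results, key=lambda t_: (-t_[1], t_[0]))[:min_genes]]
    return selected


@dataclass
class AlternativeRouteSet:
    """Alternative same-endpoint routes for one candidate trail."""

    trail: Trail
    routes: list            # list of node-id tuples
    route_scores: list | None = None
    insufficient: bool = False

    def __len__(self) -> int:
        return len(self.routes)


def build_undirected_adjacency(g) -> dict:
    """Sorted undirected neighbor lists from the directed trail graph."""
    adj: dict = {n: set() for n in g.nodes}
    for u, v in g.edges:
        adj[u].add(v)
        adj[v].add(u)
    return {n: sorted(nbrs, key=str) for n, nbrs in adj.items()}


def sample_alternative_routes(adjacency: dict, trail: Trail,
                              xy: dict,
                              k_min: int = K_MIN_ROUTES,
                              k_max: int = K_MAX_ROUTES,
                              max_attempts: int = 200,
                              min_nodes: int = MIN_NODES,
                              min_span: float = MIN_SPAN_UM,
                              max_len: int | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> AlternativeRouteSet:
    """Self-avoiding random walks from the trail's start to its end.

    Each walk steps uniformly among unvisited neighbors until it reaches the
    end, dead-ends (restart), or exceeds ``max_len`` (default 3x the trail
    length).  Distinct successful routes satisfying the length constraint and
    differing from the trail itself are collected until ``k_max`` routes or
    ``max_attempts`` walks.  Span and T-spot membership hold by construction
    (same endpoints, walk confined to the T-node graph).
    """
    rng = rng or np.random.default_rng()
    if max_len is None:
        max_len = max(3 * len(trail), min_nodes)
    s, e = trail.start, trail.end
    routes: list = []
    seen = {trail.nodes}
    for _ in range(max_attempts):
        path = [s]
        visited = {s}
        while len(path) <= max_len:
            if path[-1] == e:
                break
            options = [n for n in adjacency.get(path[-1], ()) if n not in visited]
            if not options:
                break
            nxt = options[rng.integers(len(options))]
            path.append(nxt)
            visited.add(nxt)
        if path[-1] != e or len(path) < min_nodes:
            continue
        key = tuple(path)
        if key in seen:
            continue
        seen.add(key)
        routes.append(key)
        if len(routes) >= k_max:
            break
    insufficient = len(routes) < k_min
    if insufficient:
        logger.info("trail %s -> %s: only %d alternative routes found",
                    s, e, len(routes))
    return AlternativeRouteSet(trail=trail, routes=routes,
                               insufficient=insufficient)


def mean_pairwise_correlation(node_seq, stage_expr: pd.DataFrame) -> float:
    """Mean Pearson correlation of stage-gene vectors over all node pairs.

    ``stage_expr`` is a node x stage-gene matrix of normalized expression.
    Pairs involving a zero-variance vector contribute 0 (all-dropout spots
    carry no coherence signal either way).
    """
    if stage_expr.shape[1] < 3:
        raise ValueError("need at least 3 stage genes")
    if len(node_seq) < 2:
        raise ValueError("need at least 2 nodes")
    mat = stage_expr.loc[list(node_seq)].to_numpy(float)
    n = len(node_seq)
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.debug("%d zero-variance stage vectors on route", int(degenerate.sum()))
    centered = mat - mat.mean(axis=1, keepdims=True)
    scaled = np.where(degenerate[:, None], 0.0,
                      centered / np.where(sd > 0, sd, 1.0)[:, None])
    corr = np.clip(scaled @ scaled.T / mat.shape[1], -1.0, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    return float(corr[iu, ju].mean())


def score_routes(route_set: AlternativeRouteSet,
                 stage_expr: pd.DataFrame) -> AlternativeRouteSet:
    """Fill in the mean pairwise correlation of every alternative route."""
    route_set.route_scores = [
        mean_pairwise_correlation(r, stage_expr) for r in route_set.routes
    ]
    return route_set


def finalize_trails(candidates, trail_scores, alt_sets,
                    percentile: float = SELECT_PERCENTILE,
                    k_min: int = K_MIN_ROUTES,
                    drop_insufficient: bool = True) -> tuple:
    """Apply both selection criteria; returns (final trails, report).

    A candidate is retained when its coherence score (a) is larger than all
    of its own alternative routes and (b) exceeds the ``percentile``-th
    percentile of every alternative route pooled across all candidates.
    Candidates with fewer than ``k_min`` alternatives are excluded (the
    comparison is undefined) and listed in the report.
    """
    pooled = [s for aset in alt_sets
              for s in (aset.route_scores or [])]
    threshold = np.percentile(pooled, percentile) if pooled else np.inf

    final, report = [], []
    for trail, score, aset in zip(candidates, trail_scores, alt_sets):
        if aset.route_scores is None:
            raise ValueError("alternative routes have not been scored")
        if len(aset) < k_min:
            if drop_insufficient:
                report.append((trail, "insufficient_alternatives", score))
                continue
        elif score <= max(aset.route_scores):
            report.append((trail, "below_own_alternative", score))
            continue
        if pooled and score <= threshold:
            report.append((trail, "below_pooled_percentile", score))
            continue
        final.append(trail)
    return final, report
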