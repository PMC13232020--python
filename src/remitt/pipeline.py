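"""Configuration-driven orchestration of the full trail pipeline.

``run_pipeline`` chains every stage — load, normalize, score, candidate
search, alternative-route selection, matched controls, and the systematic
statistics — and writes its tables plus a machine-readable manifest so a run
is reproducible from its saved configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controls import (N_CLUSTERS, N_CONTROL_SETS, N_PCS, cluster_spots,
                       generate_control_sets)
from .scoring import detect_t_spots, exhaustion_score, hd_aggregate
from .st_io import GenePanels, read_gmt, read_visium, normalize_counts, \
    select_variable_genes
from .trailfinder import (D_MAX_UM, ENDPOINT_FRAC, MIN_NODES, MIN_SPAN_UM,
                          build_graph, find_candidate_trails)
from .trailselect import (K_MAX_ROUTES, K_MIN_ROUTES, SELECT_PERCENTILE,
                          build_undirected_adjacency, finalize_trails,
                          mean_pairwise_correlation,
                          sample_alternative_routes, score_routes,
                          select_stage_genes)
from .trailstats import de_test, ora_fisher, shared_vgene_test, trend_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the published procedure."""

    input_path: str = ""
    output_dir: str = "remitt_out"
    platform: str = "visium"
    d_max_um: float = D_MAX_UM
    min_span_um: float = MIN_SPAN_UM
    min_nodes: int = MIN_NODES
    endpoint_frac: float = ENDPOINT_FRAC
    select_percentile: float = SELECT_PERCENTILE
    k_min_routes: int = K_MIN_ROUTES
    k_max_routes: int = K_MAX_ROUTES
    alt_route_attempts: int = 200
    k_clusters: int = N_CLUSTERS
    n_pcs: int = N_PCS
    n_control_sets: int = N_CONTROL_SETS
    fc_cut: float = 1.2
    fdr_cut: float = 0.05
    n_variable_genes: int = 3000
    hd_radius_factor: float = 5.0
    hd_tol: float | None = None
    dist_cutoff: float | None = None
    drawback_tol: float | None = None
    t_spot_threshold: float = 0.0
    drop_insufficient: bool = True
    empirical_p_convention: str = "plain"
    gmt_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    """In-memory artifacts of a pipeline run."""

    config: RunConfig
    nodes: pd.DataFrame
    candidates: list
    trails: list
    trail_scores: list
    selection_report: list
    labels: pd.Series | None = None
    control_sets: list = field(default_factory=list)
    trend_results: dict = field(default_factory=dict)
    de_table: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    shared_tcr: object = None
    shared_bcr: object = None


def trails_table(trails, scores=None) -> pd.DataFrame:
    rows = []
    for k, t in enumerate(trails):
        for i, (node, z) in enumerate(zip(t.nodes, t.z_profile), start=1):
            rows.append({
                "trail": k,
                "method": "+".join(t.methods),
                "index": i,
                "node_id": node,
                "z": z,
                "span_um": t.span_um,
                "score": None if scores is None else scores[k],
            })
    return pd.DataFrame(
        rows, columns=["trail", "method", "index", "node_id", "z",
                       "span_um", "score"])


def run_pipeline(cfg: RunConfig, ds=None, panels: GenePanels | None = None,
                 stages: str = "stats", write: bool = True) -> RunResult:
    """Run the chain up to ``stages`` (score < trails < controls < stats).

    ``ds`` may be given directly (e.g. a simulated dataset); otherwise
    ``cfg.input_path`` is read.  With ``write=True`` all tables and a run
    manifest land in ``cfg.output_dir``.
    """
    order = ["score", "trails", "controls", "stats"]
    if stages not in order:
        raise ValueError(f"stages must be one of {order}")
    depth = order.index(stages)
    panels = panels or GenePanels()

    if ds is None:
        ds = read_visium(cfg.input_path, platform=cfg.platform)
    logger.info("dataset: %d spots x %d genes", ds.n_spots, ds.n_genes)

    # --- scoring ---------------------------------------------------------
    t_spots = detect_t_spots(ds, panels, threshold=cfg.t_spot_threshold)
    if len(t_spots) == 0:
        raise RuntimeError("detect_t_spots: no T-cell-infiltrated spots found")
    nodes = exhaustion_score(ds, t_spots, panels)
    if ds.platform == "visium_hd":
        nodes = hd_aggregate(nodes, ds.pitch_um,
                             radius_factor=cfg.hd_radius_factor,
                             tol=cfg.hd_tol)
    mat = normalize_counts(ds)
    n_var = min(cfg.n_variable_genes, ds.n_genes)
    var_genes = select_variable_genes(mat, n=n_var)

    result = RunResult(config=cfg, nodes=nodes, candidates=[], trails=[],
                       trail_scores=[], selection_report=[])
    if depth == 0:
        _write_outputs(result, write)
        return result

    # --- candidate trails ------------------------------------------------
    g = build_graph(nodes, d_max=cfg.d_max_um)
    candidates = find_candidate_trails(
        g, nodes, frac=cfg.endpoint_frac, dist_cutoff=cfg.dist_cutoff,
        drawback_tol=cfg.drawback_tol, min_nodes=cfg.min_nodes,
        min_span=cfg.min_span_um)
    logger.info("%d candidate trails", len(candidates))
    result.candidates = candidates

    # --- selection against alternative routes ----------------------------
    t_mat = mat.loc[[s for s in mat.index if s in set(t_spots)]]
    t_marker_sum = t_mat[[g_ for g_ in panels.t_markers
                          if g_ in t_mat.columns]].sum(axis=1)
    stage_genes = select_stage_genes(t_mat, panels.stage_gene_candidates,
                                     t_marker_sum)
    # node-level normalized stage expression (member mean for HD nodes)
    stage_expr = _node_matrix(mat, nodes)[stage_genes]

    adjacency = build_undirected_adjacency(g)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    xy = {n: (x, y) for n, x, y in zip(nodes["node_id"], nodes["x"], nodes["y"])}
    scores, alt_sets = [], []
    for trail in candidates:
        aset = sample_alternative_routes(
            adjacency, trail, xy, k_min=cfg.k_min_routes,
            k_max=cfg.k_max_routes, max_attempts=cfg.alt_route_attempts,
            min_nodes=cfg.min_nodes, min_span=cfg.min_span_um, rng=rng)
        score_routes(aset, stage_expr)
        alt_sets.append(aset)
        scores.append(mean_pairwise_correlation(trail.nodes, stage_expr))
    trails, report = finalize_trails(
        candidates, scores, alt_sets, percentile=cfg.select_percentile,
        k_min=cfg.k_min_routes, drop_insufficient=cfg.drop_insufficient)
    logger.info("%d trails retained (%d dropped)", len(trails), len(report))
    result.trails = trails
    result.trail_scores = [scores[candidates.index(t)] for t in trails]
    result.selection_report = [(t.start, t.end, why, s) for t, why, s in report]
    if depth == 1 or not trails:
        if not trails and depth > 1:
            logger.warning("no trails survived selection; later stages skipped")
        _write_outputs(result, write)
        return result

    # --- matched controls -------------------------------------------------
    node_mat = _node_matrix(mat, nodes)
    labels = cluster_spots(node_mat[var_genes] if set(var_genes) <=
                           set(node_mat.columns) else node_mat,
                           k=cfg.k_clusters, n_pcs=cfg.n_pcs,
                           rng_seed=cfg.seed)
    while True:
        try:
            control_sets = generate_control_sets(
                trails, labels, adjacency, nodes, n_sets=cfg.n_control_sets,
                rng_seed=cfg.seed, min_span=cfg.min_span_um)
            break
        except RuntimeError as exc:
            # a trail whose cluster cannot host any matched control cannot
            # enter the control-based analyses; drop it and continue
            idx = int(str(exc).split("index ")[1].split(")")[0])
            dropped = trails.pop(idx)
            result.trail_scores.pop(idx)
            logger.warning("dropping unmatchable trail %s->%s: %s",
                           dropped.start, dropped.end, exc)
            if not trails:
                logger.warning("no matchable trails remain; later stages "
                               "skipped")
                _write_outputs(result, write)
                return result
    result.trails = trails
    result.labels = labels
    result.control_sets = control_sets
    if depth == 2:
        _write_outputs(result, write)
        return result

    # --- systematic statistics -------------------------------------------
    panel_sets = dict(panels.chemokine_sets)
    panel_sets["macrophage"] = panels.macrophage_markers
    for name, gene_set in panel_sets.items():
        try:
            result.trend_results[name] = trend_test(
                trails, node_mat, gene_set, gene_set=name)
        except ValueError as exc:
            logger.warning("trend test %s skipped: %s", name, exc)

    result.de_table = de_test(trails, control_sets, node_mat, var_genes,
                              fc_cut=cfg.fc_cut, fdr_cut=cfg.fdr_cut,
                              p_convention=cfg.empirical_p_convention)

    try:
        result.shared_tcr = shared_vgene_test(
            trails, control_sets, ds, panels.tcr_vgene_patterns,
            node_members=_hd_members(nodes),
            p_convention=cfg.empirical_p_convention)
        result.shared_bcr = shared_vgene_test(
            trails, control_sets, ds, panels.bcr_vgene_patterns,
            node_members=_hd_members(nodes),
            p_convention=cfg.empirical_p_convention)
    except ValueError as exc:
        logger.warning("shared V-gene analysis skipped: %s", exc)

    if cfg.gmt_path:
        collection = read_gmt(cfg.gmt_path)
        up = list(result.de_table.index[result.de_table["up"]])
        universe = var_genes
        up = [g_ for g_ in up if g_ in set(universe)]
        result.enrichment = ora_fisher(up, collection, universe)

    _write_outputs(result, write)
    return result


def _node_matrix(mat: pd.DataFrame, nodes: pd.DataFrame) -> pd.DataFrame:
    """Normalized expression per node (member mean for aggregated nodes)."""
    singleton = all(len(m) == 1 for m in nodes["members"])
    if singleton:
        out = mat.loc[[m[0] for m in nodes["members"]]].copy()
        out.index = nodes["node_id"].to_numpy()
        return out
    rows = [mat.loc[list(m)].mean(axis=0) for m in nodes["members"]]
    return pd.DataFrame(rows, index=nodes["node_id"].to_numpy())


def _hd_members(nodes: pd.DataFrame) -> dict | None:
    if all(len(m) == 1 and m[0] == n
           for n, m in zip(nodes["node_id"], nodes["members"])):
        return None
    return dict(zip(nodes["node_id"], nodes["members"]))


def _write_outputs(result: RunResult, write: bool) -> None:
    if not write:
        return
    cfg = result.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    nodes = result.nodes.copy()
    nodes["members"] = [";".join(map(str, m)) for m in nodes["members"]]
    nodes.to_csv(out / "nodes.csv", index=False)
    trails_table(result.candidates).to_csv(out / "candidate_trails.csv",
                                           index=False)
    trails_table(result.trails, result.trail_scores).to_csv(
        out / "trails.csv", index=False)
    pd.DataFrame(result.selection_report,
                 columns=["start", "end", "reason", "score"]).to_csv(
        out / "selection_report.csv", index=False)
    if result.labels is not None:
        result.labels.rename_axis("node_id").to_csv(out / "clusters.csv")
    if result.control_sets:
        rows = [
            {"set_id": cs.set_id, "trail": k, "index": i + 1, "node_id": n}
            for cs in result.control_sets[:10]
            for k, seq in enumerate(cs.controls)
            for i, n in enumerate(seq)
        ]
        pd.DataFrame(rows).to_csv(out / "control_sets_head.csv", index=False)
    if result.de_table is not None:
        result.de_table.to_csv(out / "de_table.csv")
    if result.trend_results:
        pd.DataFrame([
            {"gene_set": r.gene_set, "beta": r.beta, "p": r.p,
             "n_obs": r.n_obs, "n_trails": r.n_trails, "method": r.method}
            for r in result.trend_results.values()
        ]).to_csv(out / "trend_tests.csv", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.csv")
    shared = {}
    for name, res in (("tcr", result.shared_tcr), ("bcr", result.shared_bcr)):
        if res is not None:
            shared[name] = {
                "observed_median": res.observed_median,
                "null_median": float(np.median(res.null_medians)),
                "p": res.p,
                "n_vgenes": res.n_vgenes,
            }
    manifest = {
        "package": "remitt",
        "version": __version__,
        "config": cfg.to_dict(),
        "n_candidates": len(result.candidates),
        "n_trails": len(result.trails),
        "shared_vgenes": shared,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
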