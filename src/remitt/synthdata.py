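"""Synthetic Visium-like slides with planted migration trails.

The generator emulates the structure the trail-search method assumes: a
hexagonal spot lattice (110 um pitch), a subset of T-cell-infiltrated spots,
and planted trails — self-avoiding paths of adjacent T spots along which

* exhaustion-marker expression rises log-linearly with the trail index,
* chemokine panels rise log-linearly with the trail index,
* stage genes share a trail-level expression profile (coherence), and
* a trail-specific "clone" of TCR V genes is detected on every spot.

Per-spot T-cell content varies (a lognormal abundance factor), so marker
sums scale with T-cell number exactly as the exhaustion regression assumes.
Counts are negative-binomial with independent Bernoulli dropout.  Everything
is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .st_io import (
    BCR_VGENE_PATTERNS,
    CHEMOKINE_SETS,
    EXHAUSTION_MARKERS,
    MACROPHAGE_MARKERS,
    STAGE_GENE_CANDIDATES,
    STDataset,
    T_MARKERS,
)

HEX_DY = np.sqrt(3) / 2


@dataclass
class SynthConfig:
    """Study conditions for a synthetic slide.

    Defaults describe a 30x30 hex grid at 110 um pitch with 5 planted
    trails of 8 nodes, a strong exhaustion gradient (0.5 log-fold per
    step, ~30x over a trail — many noise SDs, the regime the method
    targets), a ~1.3x per-step chemokine gradient, and negative-binomial
    counts with 10% dropout.
    """

    rows: int = 30
    cols: int = 30
    pitch_um: float = 110.0
    n_trails: int = 5
    trail_length: int = 8
    t_fraction: float = 0.6
    exhaustion_step_lfc: float = 0.5
    chemokine_step_lfc: float = 0.25
    macrophage_step_lfc: float = 0.15
    stage_coherence: float = 0.6
    stage_base_mean: float = 8.0
    clone_n_vgenes: int = 4
    n_background_genes: int = 500
    t_marker_mean: float = 15.0
    exhaustion_base_mean: float = 30.0
    chemokine_base_mean: float = 2.0
    vgene_base_mean: float = 0.15
    vgene_clone_mean: float = 2.0
    background_mean_log: float = 2.0
    background_mean_sd: float = 0.7
    abundance_sd: float = 0.15
    nb_dispersion: float = 20.0
    dropout: float = 0.1
    turn_prob: float = 0.2
    min_trail_span_um: float = 500.0
    n_domains: int = 6
    domain_n_genes: int = 50
    domain_lfc: float = 1.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.trail_length < 2:
            raise ValueError("trail_length must be at least 2")
        if self.n_trails and self.trail_length > self.rows * self.cols:
            raise ValueError("planted trails cannot fit on the grid")

    def null_variant(self) -> "SynthConfig":
        """Same slide structure with every planted gradient switched off."""
        return replace(self, exhaustion_step_lfc=0.0, chemokine_step_lfc=0.0,
                       macrophage_step_lfc=0.0, stage_coherence=0.0,
                       clone_n_vgenes=0)


@dataclass
class GroundTruth:
    """What was planted: trail sequences, T status, per-gene effects."""

    trails: list                  # list of spot-id tuples, start -> end
    t_status: pd.Series           # bool per spot
    effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_hex_grid(rows: int, cols: int, pitch_um: float = 110.0) -> pd.DataFrame:
    """Interleaved hexagonal lattice; interior spots have 6 neighbors.

    Odd rows are shifted by half a pitch, rows are ``pitch * sqrt(3)/2``
    apart, so every neighbor sits exactly ``pitch_um`` away.  Returns a
    DataFrame with spot ids, array (row, col) indices and micron x/y.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r, c = r.ravel(), c.ravel()
    x = (c + 0.5 * (r % 2)) * pitch_um
    y = r * pitch_um * HEX_DY
    ids = [f"SPOT_{i:05d}" for i in range(rows * cols)]
    return pd.DataFrame({
        "spot_id": ids,
        "array_row": r,
        "array_col": 2 * c + (r % 2),  # spaceranger doubled-column convention
        "x": x,
        "y": y,
    })


def grid_adjacency(grid: pd.DataFrame, pitch_um: float) -> dict:
    """Neighbor lists at one lattice step (with a small tolerance)."""
    xy = grid[["x", "y"]].to_numpy(float)
    ids = grid["spot_id"].to_numpy()
    tree = cKDTree(xy)
    adj = {s: [] for s in ids}
    for i, j in tree.query_pairs(pitch_um * 1.01):
        adj[ids[i]].append(ids[j])
        adj[ids[j]].append(ids[i])
    return {s: sorted(v) for s, v in adj.items()}


# hex direction steps keyed by row parity, ordered circularly
# (E, NE, NW, W, SW, SE) so that d +/- 1 is a 60-degree turn
_HEX_DIRS_EVEN = [(0, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0)]
_HEX_DIRS_ODD = [(0, 1), (1, 1), (1, 0), (0, -1), (-1, 0), (-1, 1)]


def _plant_trails(grid: pd.DataFrame, cfg: SynthConfig,
                  rng: np.random.Generator) -> list:
    """Directionally persistent self-avoiding lattice paths, non-overlapping.

    Each trail starts at a random interior spot, picks one of the 6 lattice
    directions, and steps forward, turning to an adjacent direction with
    probability ``turn_prob``.  Persistence keeps planted trails close to
    straight corridors, the geometry the method targets.
    """
    by_rc = {(r, c): s for r, c, s in
             zip(grid["array_row"], grid["array_col"] // 2, grid["spot_id"])}
    # note: array_col // 2 recovers the storage column
    used: set = set()
    trails = []
    for _ in range(cfg.n_trails):
        for _attempt in range(500):
            r = int(rng.integers(1, cfg.rows - 1))
            c = int(rng.integers(1, cfg.cols - 1))
            d = int(rng.integers(6))
            path = [(r, c)]
            ok = True
            for _step in range(cfg.trail_length - 1):
                if rng.random() < cfg.turn_prob:
                    d = (d + int(rng.choice([-1, 1]))) % 6
                dirs = _HEX_DIRS_EVEN if path[-1][0] % 2 == 0 else _HEX_DIRS_ODD
                dr, dc = dirs[d]
                nxt = (path[-1][0] + dr, path[-1][1] + dc)
                if (nxt not in by_rc or nxt in path or by_rc[nxt] in used):
                    ok = False
                    break
                path.append(nxt)
            if not ok:
                continue
            spots = tuple(by_rc[p] for p in path)
            if used & set(spots):
                continue
            x0 = grid.loc[grid["spot_id"] == spots[0], ["x", "y"]].to_numpy()[0]
            x1 = grid.loc[grid["spot_id"] == spots[-1], ["x", "y"]].to_numpy()[0]
            # ground truth must itself satisfy the trail span definition
            if np.hypot(*(x1 - x0)) < cfg.min_trail_span_um:
                continue
            used.update(spots)
            trails.append(spots)
            break
        else:
            raise RuntimeError("could not place planted trails on the grid")
    return trails


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

TCR_VGENES = tuple(f"TRAV{i}" for i in range(1, 7)) \
    + tuple(f"TRAJ{i}" for i in range(1, 5)) \
    + tuple(f"TRBV{i}" for i in range(1, 7))
BCR_VGENES = ("IGHV1", "IGHV2", "IGKV1", "IGKV2", "IGLV1", "IGLV2")


def gene_universe(cfg: SynthConfig) -> list:
    chemokines = tuple(g for gs in CHEMOKINE_SETS.values() for g in gs)
    named = (T_MARKERS + EXHAUSTION_MARKERS + chemokines + MACROPHAGE_MARKERS
             + tuple(g for g in STAGE_GENE_CANDIDATES) + TCR_VGENES + BCR_VGENES)
    named = tuple(dict.fromkeys(named))
    background = tuple(f"GENE{i:04d}" for i in range(cfg.n_background_genes))
    return list(named + background)


def simulate_dataset(cfg: SynthConfig) -> tuple:
    """Simulate a slide and its ground truth under ``cfg``.

    Returns ``(STDataset, GroundTruth)``.  See the module docstring for the
    generative model.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    grid = make_hex_grid(cfg.rows, cfg.cols, cfg.pitch_um)
    n_spots = len(grid)
    genes = gene_universe(cfg)
    g_index = {g: j for j, g in enumerate(genes)}

    trails = _plant_trails(grid, cfg, rng) if cfg.n_trails else []
    trail_spots = {s for t in trails for s in t}

    spot_ids = grid["spot_id"].to_numpy()
    is_t = np.array([s in trail_spots for s in spot_ids])
    n_extra = max(0, int(round(cfg.t_fraction * n_spots)) - is_t.sum())
    free = np.flatnonzero(~is_t)
    if n_extra > len(free):
        raise ValueError("t_fraction incompatible with planted trails")
    is_t[rng.choice(free, size=n_extra, replace=False)] = True

    # per-spot T-cell abundance factor (number of T cells in the spot)
    abundance = np.where(
        is_t, np.exp(rng.normal(0.0, cfg.abundance_sd, n_spots)), 0.0)

    mu = np.zeros((n_spots, len(genes)))

    # background genes: shared lognormal baseline per gene, all spots
    bg_cols = [g_index[g] for g in genes if g.startswith("GENE")]
    bg_means = np.exp(rng.normal(cfg.background_mean_log,
                                 cfg.background_mean_sd, len(bg_cols)))
    mu[:, bg_cols] = bg_means[None, :]

    # tissue domains: horizontal bands with elevated domain-marker genes,
    # giving expression clusters a spatially contiguous footprint
    domain_of_spot = np.minimum(
        (grid["array_row"].to_numpy() * cfg.n_domains) // cfg.rows,
        cfg.n_domains - 1) if cfg.n_domains > 1 else np.zeros(n_spots, int)
    if cfg.n_domains > 1 and cfg.domain_n_genes > 0:
        base_total = mu[0, bg_cols].sum()
        for dom in range(cfg.n_domains):
            picked = rng.choice(bg_cols,
                                size=min(cfg.domain_n_genes, len(bg_cols)),
                                replace=False)
            rows_in = np.flatnonzero(domain_of_spot == dom)
            mu[np.ix_(rows_in, picked)] *= np.exp(cfg.domain_lfc)
            # compositional signature: rescale so the expected background
            # library size is identical in every domain
            factor = base_total / mu[rows_in[0], bg_cols].sum()
            mu[np.ix_(rows_in, bg_cols)] *= factor

    t_idx = np.flatnonzero(is_t)
    trail_index = {}  # spot -> (trail number, 0-based step)
    for k, t in enumerate(trails):
        for i, s in enumerate(t):
            trail_index[s] = (k, i)

    # trail-level stage profiles (the planted coherence signal)
    stage_genes = [g for g in STAGE_GENE_CANDIDATES]
    trail_stage = rng.normal(0.0, cfg.stage_coherence,
                             (max(len(trails), 1), len(stage_genes)))
    clone_sets = []
    for k in range(len(trails)):
        if cfg.clone_n_vgenes:
            clone_sets.append(tuple(
                rng.choice(TCR_VGENES, size=min(cfg.clone_n_vgenes,
                                                len(TCR_VGENES)),
                           replace=False)))
        else:
            clone_sets.append(())

    for i in t_idx:
        s = spot_ids[i]
        a = abundance[i]
        on_trail = s in trail_index
        step = trail_index[s][1] if on_trail else 0
        k = trail_index[s][0] if on_trail else -1

        for g in T_MARKERS:
            mu[i, g_index[g]] = cfg.t_marker_mean * a
        # trails run from well below the resident off-trail baseline
        # (newly entered cells) to well above it (exhausted): the planted
        # log-linear gradient is centered on the baseline
        exh = cfg.exhaustion_base_mean * a
        if on_trail:
            mid = (cfg.trail_length - 1) / 2.0
            exh *= np.exp(cfg.exhaustion_step_lfc * (step - mid))
        for g in EXHAUSTION_MARKERS:
            mu[i, g_index[g]] = exh
        for gs in CHEMOKINE_SETS.values():
            for g in gs:
                base = cfg.chemokine_base_mean
                if on_trail:
                    base *= np.exp(cfg.chemokine_step_lfc * step)
                mu[i, g_index[g]] = base
        for g in MACROPHAGE_MARKERS:
            base = cfg.chemokine_base_mean
            if on_trail:
                base *= np.exp(cfg.macrophage_step_lfc * step)
            mu[i, g_index[g]] = base
        if on_trail:
            eta = trail_stage[k] + rng.normal(0.0, 0.2, len(stage_genes))
        else:
            eta = rng.normal(0.0, max(cfg.stage_coherence, 1e-12),
                             len(stage_genes))
        for g, e in zip(stage_genes, eta):
            mu[i, g_index[g]] = cfg.stage_base_mean * a * np.exp(e)
        for g in TCR_VGENES + BCR_VGENES:
            mu[i, g_index[g]] = cfg.vgene_base_mean * a
        if on_trail:
            for g in clone_sets[k]:
                mu[i, g_index[g]] = cfg.vgene_clone_mean * a

    counts = _sample_nb(mu, cfg.nb_dispersion, cfg.dropout, rng)

    ds = STDataset(
        counts=sp.csr_matrix(counts),
        spot_ids=spot_ids,
        xy=grid[["x", "y"]].to_numpy(float),
        gene_names=np.array(genes, dtype=object),
        platform="visium",
        pitch_um=cfg.pitch_um,
    )
    gt = GroundTruth(
        trails=trails,
        t_status=pd.Series(is_t, index=spot_ids),
        effects={
            "exhaustion_step_lfc": cfg.exhaustion_step_lfc,
            "chemokine_step_lfc": cfg.chemokine_step_lfc,
            "macrophage_step_lfc": cfg.macrophage_step_lfc,
            "clone_vgenes": clone_sets,
            "abundance": pd.Series(abundance, index=spot_ids),
        },
    )
    return ds, gt


def nb_mean_after_dropout(mu: float, dropout: float) -> float:
    """Closed-form expected count: NB mean thinned by Bernoulli dropout."""
    return mu * (1.0 - dropout)


def _sample_nb(mu: np.ndarray, dispersion: float, dropout: float,
               rng: np.random.Generator) -> np.ndarray:
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    counts[pos] = rng.negative_binomial(dispersion, p)
    if dropout > 0:
        keep = rng.random(counts.shape) >= dropout
        counts = counts * keep
    return counts


def simulate_trend_data(n_trails: int = 20, length: int = 7,
                        step_lfc: float = 0.0, base_mean: float = 5.0,
                        intercept_sd: float = 0.5,
                        dispersion: float = 5.0,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Long-format panel expression from a random-intercept NB model.

    Used to study the trend test: each trail draws a lognormal intercept,
    and the expected expression at index ``i`` (1-based) is
    ``base_mean * exp(intercept) * exp(step_lfc * (i - 1))``.  With
    ``step_lfc = 0`` this is the calibration null.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for t in range(n_trails):
        b = rng.normal(0.0, intercept_sd)
        for i in range(1, length + 1):
            m = base_mean * np.exp(b + step_lfc * (i - 1))
            p = dispersion / (dispersion + m)
            rows.append((t, i, float(rng.negative_binomial(dispersion, p))))
    return pd.DataFrame(rows, columns=["trail", "index", "y"])


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_visium_like(ds: STDataset, gt: GroundTruth | None, path,
                      microns_per_pixel: float = 0.5) -> Path:
    """Write a spaceranger-style directory readable by ``st_io.read_visium``.

    Emits matrix.mtx (genes x barcodes), features.tsv, barcodes.tsv, a v2
    headered tissue-positions table under spatial/, a scale-factor JSON, and
    (when ground truth is given) a sidecar ``ground_truth_trails.csv``.
    """
    base = Path(path)
    (base / "spatial").mkdir(parents=True, exist_ok=True)

    scipy.io.mmwrite(str(base / "matrix.mtx"), sp.coo_matrix(ds.counts.T),
                     field="integer")
    with open(base / "features.tsv", "w") as fh:
        for g in ds.gene_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(base / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{s}\n" for s in ds.spot_ids)

    pitch = ds.pitch_um
    pos = pd.DataFrame({
        "barcode": ds.spot_ids,
        "in_tissue": 1,
        "array_row": np.round(ds.xy[:, 1] / (pitch * HEX_DY)).astype(int),
        "array_col": np.round(2 * ds.xy[:, 0] / pitch).astype(int),
        "pxl_row_in_fullres": ds.xy[:, 1] / microns_per_pixel,
        "pxl_col_in_fullres": ds.xy[:, 0] / microns_per_pixel,
    })
    pos.to_csv(base / "spatial" / "tissue_positions.csv", index=False)
    with open(base / "spatial" / "scalefactors_json.json", "w") as fh:
        json.dump({"microns_per_pixel": microns_per_pixel,
                   "spot_diameter_fullres": 55.0 / microns_per_pixel}, fh)

    if gt is not None:
        rows = [
            {"trail": k, "index": i + 1, "spot_id": s}
            for k, t in enumerate(gt.trails) for i, s in enumerate(t)
        ]
        pd.DataFrame(rows, columns=["trail", "index", "spot_id"]).to_csv(
            base / "ground_truth_trails.csv", index=False)
        gt.t_status.rename("is_t_spot").to_csv(base / "ground_truth_t_spots.csv")
    return base
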