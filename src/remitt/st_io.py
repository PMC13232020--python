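"""Reading spaceranger-style spatial transcriptomics outputs.

This module defines the in-memory data model (:class:`STDataset`), the gene
panel configuration (:class:`GenePanels`), GMT gene-set collections, per-spot
TPM normalization, and variable-gene selection.  All geometry downstream is
expressed in microns; array (row, col) coordinates are converted exactly once
at load time.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: diameter-independent default center-to-center spot spacing on Visium slides
DEFAULT_PITCH_UM = 110.0

#: physical capture-spot diameter on standard Visium, used to convert the
#: spaceranger ``spot_diameter_fullres`` scale factor into microns per pixel
VISIUM_SPOT_DIAMETER_UM = 55.0


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class STDataset:
    """A spatial expression slide: spots/pixels x genes counts plus geometry.

    Attributes
    ----------
    counts:
        Sparse CSR matrix of raw UMI counts, spots x genes.
    spot_ids:
        Unique spot barcodes, aligned with count rows.
    xy:
        ``(n_spots, 2)`` spot center coordinates in microns.
    gene_names:
        Unique gene symbols, aligned with count columns.
    platform:
        ``"visium"`` or ``"visium_hd"``.
    pitch_um:
        Center-to-center spot/pixel spacing in microns.
    """

    counts: sp.csr_matrix
    spot_ids: np.ndarray
    xy: np.ndarray
    gene_names: np.ndarray
    platform: str = "visium"
    pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.xy = np.asarray(self.xy, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(
                f"barcodes ({len(self.spot_ids)}) do not match matrix rows ({n})"
            )
        if len(self.gene_names) != g:
            raise ValueError(
                f"features ({len(self.gene_names)}) do not match matrix columns ({g})"
            )
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot ids are not unique")
        if len(set(self.gene_names)) != g:
            raise ValueError("gene names are not unique")
        if self.xy.shape != (n, 2):
            raise ValueError("xy must be (n_spots, 2)")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite spot coordinates")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.platform not in ("visium", "visium_hd"):
            raise ValueError(f"unknown platform {self.platform!r}")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def umi_total(self) -> np.ndarray:
        """Per-spot total UMI count (row sums of ``counts``)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_indices(self, genes) -> np.ndarray:
        """Column indices of the requested genes that exist on this slide."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def marker_counts(self, genes) -> np.ndarray:
        """Per-spot summed raw counts over the available ``genes``."""
        idx = self.gene_indices(genes)
        if idx.size == 0:
            return np.zeros(self.n_spots)
        return np.asarray(self.counts[:, idx].sum(axis=1)).ravel()

    def subset_spots(self, mask_or_ids) -> "STDataset":
        """Restrict to a boolean mask or an explicit list of spot ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            order = {s: i for i, s in enumerate(self.spot_ids)}
            idx = np.array([order[s] for s in mask_or_ids], dtype=int)
        return STDataset(
            counts=self.counts[idx],
            spot_ids=self.spot_ids[idx],
            xy=self.xy[idx],
            gene_names=self.gene_names,
            platform=self.platform,
            pitch_um=self.pitch_um,
        )


# The marker panels below follow the standard immunology usage: pan-T surface
# markers for infiltration calling, canonical checkpoint/exhaustion genes for
# the exhaustion readout, chemokine axes known to recruit T cells, macrophage
# lineage markers, and TCR/BCR variable-gene name prefixes as clonal
# surrogates.
T_MARKERS = ("CD8A", "CD8B", "CD4", "CD3D", "CD3E", "CD3G")
EXHAUSTION_MARKERS = ("PDCD1", "LAG3", "HAVCR2", "TIGIT", "CTLA4", "ENTPD1", "TOX")
CHEMOKINE_SETS = {
    "cxcl9_10_11": ("CXCL9", "CXCL10", "CXCL11"),
    "ccl4_5": ("CCL4", "CCL5"),
    "cxcl16": ("CXCL16",),
}
MACROPHAGE_MARKERS = ("CD68", "CD163", "CD80", "CD14")
# T cell state / stage markers: naive-memory (CCR7, SELL, TCF7, LEF1, IL7R),
# effector-cytotoxicity (GZMK, GZMB, PRF1, NKG7, IFNG), activation and
# residency (CD69, ICOS, TNFRSF9, ITGAE, CXCR6), Treg (FOXP3, IL2RA) and
# proliferation (MKI67).
STAGE_GENE_CANDIDATES = (
    "CCR7", "SELL", "TCF7", "LEF1", "IL7R", "CD28",
    "GZMK", "GZMB", "PRF1", "NKG7", "IFNG", "CST7",
    "CD69", "ICOS", "TNFRSF9", "ITGAE", "CXCR6",
    "FOXP3", "IL2RA", "MKI67",
    "KLRG1", "CX3CR1", "TBX21", "EOMES", "ZNF683",
    "ITGA1", "CD101", "KLRB1", "TNFRSF4", "BATF",
)
TCR_VGENE_PATTERNS = ("TRAV", "TRAJ", "TRBV")
BCR_VGENE_PATTERNS = ("IGHV", "IGKV", "IGLV")


@dataclass
class GenePanels:
    """Gene panel configuration used throughout the pipeline."""

    t_markers: tuple = T_MARKERS
    exhaustion_markers: tuple = EXHAUSTION_MARKERS
    stage_gene_candidates: tuple = STAGE_GENE_CANDIDATES
    chemokine_sets: dict = field(default_factory=lambda: dict(CHEMOKINE_SETS))
    macrophage_markers: tuple = MACROPHAGE_MARKERS
    tcr_vgene_patterns: tuple = TCR_VGENE_PATTERNS
    bcr_vgene_patterns: tuple = BCR_VGENE_PATTERNS

    def __post_init__(self) -> None:
        for name in ("t_markers", "exhaustion_markers", "stage_gene_candidates"):
            if not getattr(self, name):
                raise ValueError(f"gene panel {name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional background universe."""

    sets: dict
    universe: list | None = None

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate set names")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = tuple(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find(base: Path, names) -> Path:
    for name in names:
        for candidate in (base / name, base / "spatial" / name,
                          base / "filtered_feature_bc_matrix" / name):
            if candidate.exists():
                return candidate
    raise FileNotFoundError(
        f"none of {list(names)} found under {base} (or its spatial/ subdir)"
    )


def _read_positions(base: Path) -> pd.DataFrame:
    """Parse tissue positions in either spaceranger dialect.

    v1 is headerless ``tissue_positions_list.csv``; v2 is headered
    ``tissue_positions.csv``.  Both carry barcode, in-tissue flag, array
    row/col and full-resolution pixel row/col.
    """
    cols = ["barcode", "in_tissue", "array_row", "array_col",
            "pxl_row_in_fullres", "pxl_col_in_fullres"]
    path = _find(base, ("tissue_positions.csv", "tissue_positions_list.csv"))
    first = pd.read_csv(path, header=None, nrows=1)
    if first.iloc[0, 0] == "barcode":  # v2 headered dialect
        df = pd.read_csv(path)
        df = df.rename(columns={c: c.strip() for c in df.columns})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing position columns {missing}")
        df = df[cols]
    else:
        df = pd.read_csv(path, header=None, names=cols)
    return df


def read_visium(path, platform: str = "visium",
                pitch_um: float = DEFAULT_PITCH_UM) -> STDataset:
    """Read a spaceranger-style output directory into an :class:`STDataset`.

    Expects an MTX count matrix (genes x barcodes) with features/barcodes
    lists and a tissue-positions table.  Spots flagged out-of-tissue are
    dropped.  Micron coordinates come from full-resolution pixel coordinates
    scaled by the scale-factor metadata when present; otherwise from the
    array (row, col) coordinates on the standard interleaved hexagonal
    layout: ``x = col * pitch/2``, ``y = row * pitch * sqrt(3)/2``.
    """
    base = Path(path)
    if not base.is_dir():
        raise FileNotFoundError(f"not a directory: {base}")

    mtx_path = _find(base, ("matrix.mtx", "matrix.mtx.gz"))
    feat_path = _find(base, ("features.tsv", "features.tsv.gz",
                             "genes.tsv", "genes.tsv.gz"))
    bc_path = _find(base, ("barcodes.tsv", "barcodes.tsv.gz"))

    mat = scipy.io.mmread(str(mtx_path)).tocsr().T.tocsr()  # spots x genes
    with _open_text(feat_path) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None)
    with _open_text(bc_path) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)[0].astype(str).to_numpy()
    # features.tsv carries (id, symbol, type); bare one-column lists accepted
    gene_names = feats[1 if feats.shape[1] > 1 else 0].astype(str).to_numpy()

    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[0]} barcodes but {bc_path.name} lists "
            f"{len(barcodes)}"
        )
    if mat.shape[1] != len(gene_names):
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but {feat_path.name} lists "
            f"{len(gene_names)}"
        )

    pos = _read_positions(base)
    pos = pos.set_index("barcode").reindex(barcodes)
    if pos["in_tissue"].isna().any():
        missing = [b for b in barcodes if b not in pos.index]
        raise ValueError(f"barcodes absent from tissue positions: {missing[:5]}")

    microns_per_pixel = _read_microns_per_pixel(base)
    if microns_per_pixel is not None:
        xy = np.column_stack([
            pos["pxl_col_in_fullres"].to_numpy(float) * microns_per_pixel,
            pos["pxl_row_in_fullres"].to_numpy(float) * microns_per_pixel,
        ])
    else:
        xy = np.column_stack([
            pos["array_col"].to_numpy(float) * pitch_um / 2.0,
            pos["array_row"].to_numpy(float) * pitch_um * np.sqrt(3) / 2.0,
        ])

    keep = pos["in_tissue"].to_numpy(int) == 1
    return STDataset(
        counts=mat[keep],
        spot_ids=barcodes[keep],
        xy=xy[keep],
        gene_names=gene_names,
        platform=platform,
        pitch_um=pitch_um,
    )


def _read_microns_per_pixel(base: Path) -> float | None:
    try:
        sf_path = _find(base, ("scalefactors_json.json",))
    except FileNotFoundError:
        return None
    with open(sf_path) as fh:
        sf = json.load(fh)
    if "microns_per_pixel" in sf:
        return float(sf["microns_per_pixel"])
    if "spot_diameter_fullres" in sf:
        return VISIUM_SPOT_DIAMETER_UM / float(sf["spot_diameter_fullres"])
    return None


# ---------------------------------------------------------------------------
# normalization and gene selection
# ---------------------------------------------------------------------------

def normalize_counts(ds: STDataset, scale: float = 1e6) -> pd.DataFrame:
    """Per-spot TPM-like scaling: each spot's counts rescaled to sum to 1e6.

    Spots with zero total UMI cannot be normalized and are dropped with a
    warning.  Returns a dense spots x genes DataFrame indexed by spot id.
    """
    totals = ds.umi_total.astype(float)
    if not totals.any():
        raise ValueError("all-zero count matrix: nothing to normalize")
    keep = totals > 0
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("dropping %d zero-UMI spots during normalization", dropped)
        warnings.warn(f"dropped {dropped} zero-UMI spots", stacklevel=2)
    dense = np.asarray(ds.counts[np.flatnonzero(keep)].todense(), dtype=float)
    dense *= scale / totals[keep, None]
    return pd.DataFrame(dense, index=ds.spot_ids[keep], columns=ds.gene_names)


def select_variable_genes(mat: pd.DataFrame, n: int = 3000) -> list:
    """Top-``n`` genes by variance of log1p-normalized expression.

    Deterministic: ties are broken by gene name so that shuffling the column
    order never changes membership.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > mat.shape[1]:
        raise ValueError(f"requested {n} genes but matrix has {mat.shape[1]}")
    disp = np.log1p(mat).var(axis=0, ddof=1)
    order = sorted(mat.columns, key=lambda g: (-disp[g], g))
    return list(order[:n])


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a tab-separated GMT file: name, description, member genes."""
    sets = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name = fields[0]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (descriptions left blank)."""
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
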