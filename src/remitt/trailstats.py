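"""Statistics on finalized migration trails.

* gradient trend tests along trails (linear mixed model, random intercept
  per trail) for chemokine and macrophage panels;
* empirical differential expression of variable genes on trails versus the
  matched-control null, with Benjamini-Hochberg adjustment;
* shared TCR/BCR variable-gene analysis between consecutive spots;
* Fisher-exact over-representation of up-called genes in GMT gene sets;
* phenotype ranking of up-called genes across a cluster-mean table from
  single-cell data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .controls import empirical_p
from .st_io import GeneSetCollection, STDataset

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# trend tests
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    """Mixed-model slope of expression on the 1-based trail spot index."""

    gene_set: str
    beta: float
    p: float
    n_obs: int
    n_trails: int
    variance_components: dict = field(default_factory=dict)
    method: str = "mixedlm"

    @property
    def significant_increase(self) -> bool:
        return self.beta > 0 and self.p < 0.05


def trails_long_table(trails, mat: pd.DataFrame, genes) -> pd.DataFrame:
    """Long-format (trail, index, y) table of summed panel expression."""
    genes = [g for g in genes if g in mat.columns]
    if not genes:
        raise ValueError("none of the requested genes are in the matrix")
    rows = []
    for t_id, trail in enumerate(trails):
        node_seq = trail.nodes if hasattr(trail, "nodes") else trail
        expr = mat.loc[list(node_seq), genes].sum(axis=1).to_numpy(float)
        for i, y in enumerate(expr, start=1):
            rows.append((t_id, i, y))
    return pd.DataFrame(rows, columns=["trail", "index", "y"])


def fit_index_trend(long: pd.DataFrame, gene_set: str = "") -> TrendResult:
    """Random-intercept mixed model of ``y`` on the spot index, ML fit.

    Falls back to per-trail OLS slopes with a one-sample two-sided t test
    when the mixed model cannot be fitted.
    """
    n_trails = long["trail"].nunique()
    if n_trails < 2:
        raise ValueError("need at least 2 trails for the trend test")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(long["y"].to_numpy(float),
                            np.column_stack([np.ones(len(long)),
                                             long["index"].to_numpy(float)]),
                            groups=long["trail"].to_numpy())
            fit = model.fit(reml=False)
        beta = float(fit.params[1])
        p = float(fit.pvalues[1])
        if not np.isfinite(p):
            raise ValueError("non-finite Wald p")
        return TrendResult(
            gene_set=gene_set, beta=beta, p=p, n_obs=len(long),
            n_trails=n_trails,
            variance_components={
                "group_var": float(np.asarray(fit.cov_re).ravel()[0]),
                "resid_var": float(fit.scale),
            },
        )
    except Exception as exc:  # singular / non-converged fits
        logger.warning("mixed model failed (%s); falling back to per-trail OLS",
                       exc)
        slopes = []
        for _, grp in long.groupby("trail"):
            if grp["index"].nunique() < 2:
                continue
            slopes.append(np.polyfit(grp["index"], grp["y"], 1)[0])
        t, p = stats.ttest_1samp(slopes, 0.0)
        return TrendResult(gene_set=gene_set, beta=float(np.mean(slopes)),
                           p=float(p), n_obs=len(long), n_trails=n_trails,
                           method="per_trail_ols")


def trend_test(trails, mat: pd.DataFrame, genes, gene_set: str = "") -> TrendResult:
    """Trend of summed panel expression along trails (see module docstring).

    Each trail contributes its spots with 1-based indices; the trail identity
    enters as a random intercept, and the reported ``beta`` is the fixed
    slope on the index with its two-sided Wald p.
    """
    long = trails_long_table(trails, mat, genes)
    if (long.groupby("trail").size() < 3).any():
        raise ValueError("every trail needs at least 3 spots for the trend test")
    return fit_index_trend(long, gene_set=gene_set)


# ---------------------------------------------------------------------------
# empirical differential expression
# ---------------------------------------------------------------------------

def _mean_expression(spot_lists, mat: pd.DataFrame, genes) -> np.ndarray:
    spots = [s for seq in spot_lists for s in seq]
    return mat.loc[spots, genes].to_numpy(float).mean(axis=0)


def de_test(trails, control_sets, mat: pd.DataFrame, genes,
            fc_cut: float = 1.2, fdr_cut: float = 0.05,
            p_convention: str = "plain") -> pd.DataFrame:
    """Empirical differential expression of ``genes`` on trails vs controls.

    Per gene, the observed statistic is its mean normalized expression over
    all on-trail spots; the null is the same statistic in each matched
    control set.  Two-sided empirical p-values are BH-adjusted across genes;
    a gene is called up when adjusted p < ``fdr_cut``, fold change >
    ``fc_cut`` and the observed mean exceeds the null mean.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in mat.columns]
    if missing:
        logger.warning("skipping %d genes absent from the matrix", len(missing))
        genes = [g for g in genes if g in mat.columns]
    if not genes:
        raise ValueError("no requested genes present in the matrix")

    trail_seqs = [t.nodes if hasattr(t, "nodes") else t for t in trails]
    observed = _mean_expression(trail_seqs, mat, genes)
    null = np.stack([
        _mean_expression(cs.controls, mat, genes) for cs in control_sets
    ])  # sets x genes

    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(null_mean > 0, observed / null_mean,
                      np.where(observed > 0, np.inf, 1.0))
    pvals = np.array([
        empirical_p(observed[j], null[:, j], convention=p_convention)
        for j in range(len(genes))
    ])
    padj = bh_adjust(pvals)
    table = pd.DataFrame({
        "gene": genes,
        "observed_mean": observed,
        "null_mean": null_mean,
        "fold_change": fc,
        "p_empirical": pvals,
        "p_adjusted": padj,
    }).set_index("gene")
    table["up"] = ((table["p_adjusted"] < fdr_cut)
                   & (table["fold_change"] > fc_cut)
                   & (table["observed_mean"] > table["null_mean"]))
    table["down"] = ((table["p_adjusted"] < fdr_cut)
                     & (table["fold_change"] < 1.0 / fc_cut)
                     & (table["observed_mean"] < table["null_mean"]))
    return table.sort_values("p_adjusted")


# ---------------------------------------------------------------------------
# shared V genes
# ---------------------------------------------------------------------------

@dataclass
class SharedVGeneResult:
    observed_median: float
    null_medians: np.ndarray
    p: float
    n_vgenes: int
    per_trail_means: list


def _detected_vgene_sets(ds: STDataset, vgene_idx: np.ndarray) -> dict:
    sub = ds.counts[:, vgene_idx]
    detected = {}
    for i, spot in enumerate(ds.spot_ids):
        row = sub[i]
        detected[spot] = frozenset(row.indices)
    return detected


def _mean_shared(seq, detected: dict) -> float:
    pairs = list(zip(seq[:-1], seq[1:]))
    if not pairs:
        return 0.0
    # spot-level sharing: a V gene counts when detected (count > 0) in both
    return float(np.mean([len(detected[u] & detected[v]) for u, v in pairs]))


def shared_vgene_test(trails, control_sets, ds: STDataset, patterns,
                      node_members: dict | None = None,
                      p_convention: str = "plain") -> SharedVGeneResult:
    """Shared TCR/BCR variable genes between consecutive trail spots.

    A V gene is *shared* by a consecutive pair when its raw count is nonzero
    in both spots.  Per trail: the mean shared count over consecutive pairs;
    the observed statistic is the median over trails, compared two-sidedly
    against the same statistic in each control set.  ``patterns`` are gene
    name prefixes (e.g. ``("TRAV", "TRAJ", "TRBV")``); pass the BCR prefixes
    for the B cell analysis.
    """
    names = ds.gene_names
    vgene_idx = np.array(
        [j for j, g in enumerate(names)
         if any(str(g).startswith(p) for p in patterns)], dtype=int)
    if vgene_idx.size == 0:
        prefixes = sorted({str(g)[:4] for g in names})
        raise ValueError(
            f"no genes match patterns {tuple(patterns)}; available prefixes "
            f"include {prefixes[:20]}"
        )
    detected = _detected_vgene_sets(ds, vgene_idx)
    if node_members:
        # aggregated HD nodes: a V gene is detected in a node when detected
        # in any member pixel
        node_detected = {}
        for node, members in node_members.items():
            acc = frozenset()
            for m in members:
                acc |= detected[m]
            node_detected[node] = acc
        detected = {**detected, **node_detected}

    trail_seqs = [t.nodes if hasattr(t, "nodes") else t for t in trails]
    per_trail = [_mean_shared(seq, detected) for seq in trail_seqs]
    observed = float(np.median(per_trail))
    null = np.array([
        np.median([_mean_shared(seq, detected) for seq in cs.controls])
        for cs in control_sets
    ])
    p = empirical_p(observed, null, convention=p_convention)
    return SharedVGeneResult(observed_median=observed, null_medians=null,
                             p=p, n_vgenes=int(vgene_idx.size),
                             per_trail_means=per_trail)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_fisher(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of ``query`` genes in each set.

    The 2x2 table for a set counts universe genes by query membership and
    set membership; the p-value is the upper (enrichment) tail.  BH
    adjustment across sets; sorted by adjusted p.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = set(query)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in sets.sets.items():
        members = set(members) & uni
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(uni) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), float(p)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    table["p_adjusted"] = bh_adjust(table["p"])
    return table.sort_values(["p_adjusted", "p", "set"]).set_index("set")


# ---------------------------------------------------------------------------
# phenotype ranking
# ---------------------------------------------------------------------------

def phenotype_rank(up_genes, cluster_means: pd.DataFrame) -> pd.DataFrame:
    """Rank clusters by where trail-upregulated genes peak.

    ``cluster_means`` is a cluster x gene table of mean expression (e.g.
    from annotated single-cell clusters).  For every up gene the cluster
    means are ranked ascending (largest mean gets the top rank, ties share
    the average rank).  Each cluster is summarized by the distribution of
    its ranks across the up genes; clusters are ordered by median rank,
    descending, so the most enriched phenotype comes first.
    """
    if cluster_means.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    genes = [g for g in up_genes if g in cluster_means.columns]
    if not genes:
        raise ValueError("no up-regulated gene overlaps the cluster-mean table")
    ranks = cluster_means[genes].rank(axis=0, method="average", ascending=True)
    summary = pd.DataFrame({
        "median_rank": ranks.median(axis=1),
        "mean_rank": ranks.mean(axis=1),
        "n_genes": len(genes),
        "n_top_ranks": (ranks == ranks.max(axis=0)).sum(axis=1),
    })
    summary.attrs["ranks"] = ranks
    return summary.sort_values("median_rank", ascending=False)
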