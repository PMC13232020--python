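import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from remitt.controls import ControlSet
from remitt.st_io import GeneSetCollection
from remitt.synthdata import simulate_trend_data
from remitt.trailstats import (bh_adjust, de_test, fit_index_trend,
                               ora_fisher, phenotype_rank, shared_vgene_test,
                               trend_test)

from conftest import make_dataset


def _mk_trails(seqs):
    return [tuple(s) for s in seqs]


class TestTrendTest:
    def test_exact_linear_expression_recovers_unit_slope(self):
        mat = pd.DataFrame({"CXCL9": np.tile(np.arange(1, 8.0), 3)},
                           index=[f"S{i}" for i in range(21)])
        trails = _mk_trails([[f"S{i}" for i in range(k * 7, k * 7 + 7)]
                             for k in range(3)])
        res = trend_test(trails, mat, ["CXCL9"])
        assert res.beta == pytest.approx(1.0, abs=1e-6)
        assert res.variance_components.get("resid_var", 0) < 1e-8

    def test_recovers_generative_slope(self):
        """Slope estimates center on the generative log-linear gradient."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            long = simulate_trend_data(n_trails=20, length=7, step_lfc=0.0,
                                       base_mean=20.0, rng=rng)
            long["y"] += 0.5 * (long["index"] - 1)  # additive slope 0.5
            res = fit_index_trend(long)
            se = abs(res.beta - 0.5) / max(stats.norm.ppf(0.975), 1)
            hits += abs(res.beta - 0.5) < 1.2  # generous CI at this n
        assert hits >= 18

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for rep in range(60):
            rng = np.random.default_rng(5000 + rep)
            long = simulate_trend_data(n_trails=15, length=7, step_lfc=0.0,
                                       rng=rng)
            pvals.append(fit_index_trend(long).p)
        assert 0.0 <= np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_requires_multiple_trails(self):
        mat = pd.DataFrame({"CXCL9": np.arange(7.0)},
                           index=[f"S{i}" for i in range(7)])
        with pytest.raises(ValueError):
            trend_test(_mk_trails([[f"S{i}" for i in range(7)]]), mat,
                       ["CXCL9"])

    def test_default_panels_match_published_lists(self, panels):
        assert panels.chemokine_sets["cxcl9_10_11"] == ("CXCL9", "CXCL10",
                                                        "CXCL11")
        assert panels.chemokine_sets["ccl4_5"] == ("CCL4", "CCL5")
        assert panels.chemokine_sets["cxcl16"] == ("CXCL16",)
        assert panels.macrophage_markers == ("CD68", "CD163", "CD80", "CD14")


def _control_sets(seqs_per_set):
    return [ControlSet(set_id=i, controls=[tuple(s) for s in seqs])
            for i, seqs in enumerate(seqs_per_set)]


class TestDeTest:
    def test_constant_gene_not_called(self, rng):
        idx = [f"S{i}" for i in range(20)]
        mat = pd.DataFrame({"FLAT": 5.0, "VAR": rng.uniform(0, 10, 20)},
                           index=idx)
        trails = _mk_trails([idx[:5]])
        sets = _control_sets([[idx[i:i + 5]] for i in range(1, 15)])
        table = de_test(trails, sets, mat, ["FLAT", "VAR"])
        row = table.loc["FLAT"]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p_empirical"] == pytest.approx(1.0)
        assert not row["up"]

    def test_planted_gene_is_called_up(self, rng):
        idx = [f"S{i}" for i in range(60)]
        base = pd.DataFrame(
            rng.uniform(5, 15, size=(60, 30)), index=idx,
            columns=[f"G{j}" for j in range(30)])
        trail_spots = idx[:6]
        base.loc[trail_spots, "G0"] *= 3.0  # planted 3x elevation
        trails = _mk_trails([trail_spots])
        sets = _control_sets([
            [list(rng.choice(idx[6:], size=6, replace=False))]
            for _ in range(200)
        ])
        table = de_test(trails, sets, base, list(base.columns))
        assert bool(table.loc["G0", "up"])
        assert table.loc["G0", "p_adjusted"] < 0.05
        assert table.loc["G0", "fold_change"] > 1.2

    def test_adjusted_p_dominates_raw(self, rng):
        idx = [f"S{i}" for i in range(40)]
        mat = pd.DataFrame(rng.uniform(0, 10, size=(40, 25)), index=idx,
                           columns=[f"G{j}" for j in range(25)])
        trails = _mk_trails([idx[:5]])
        sets = _control_sets([
            [list(rng.choice(idx[5:], size=5, replace=False))]
            for _ in range(50)
        ])
        table = de_test(trails, sets, mat, list(mat.columns))
        assert (table["p_adjusted"] >= table["p_empirical"] - 1e-12).all()

    def test_missing_gene_skipped_with_warning(self, rng, caplog):
        idx = [f"S{i}" for i in range(10)]
        mat = pd.DataFrame({"G0": rng.uniform(0, 1, 10)}, index=idx)
        trails = _mk_trails([idx[:3]])
        sets = _control_sets([[idx[3:6]], [idx[4:7]]])
        table = de_test(trails, sets, mat, ["G0", "ABSENT"])
        assert list(table.index) == ["G0"]


class TestSharedVGenes:
    @staticmethod
    def _ds(rows, genes):
        return make_dataset(rows, gene_names=genes)

    def test_full_sharing_gives_panel_size(self):
        genes = ["TRAV1", "TRAV2", "TRBV1", "TRAJ1", "GENE1"]
        counts = np.ones((4, 5), dtype=int)
        counts[:, 4] = 0
        ds = self._ds(counts, genes)
        trails = _mk_trails([["S0", "S1", "S2", "S3"]])
        sets = _control_sets([[["S3", "S2", "S1", "S0"]]])
        res = shared_vgene_test(trails, sets, ds, ("TRAV", "TRAJ", "TRBV"))
        assert res.observed_median == pytest.approx(4.0)

    def test_set_intersection_oracle(self):
        # spots detect V-gene sets {A,B}, {B,C}, {C}: overlaps 1 and 1
        genes = ["TRAVA", "TRAVB", "TRAVC"]
        counts = np.array([[2, 1, 0], [0, 3, 5], [0, 0, 1]])
        ds = self._ds(counts, genes)
        trails = _mk_trails([["S0", "S1", "S2"]])
        sets = _control_sets([[["S2", "S1", "S0"]]])
        res = shared_vgene_test(trails, sets, ds, ("TRAV",))
        assert res.per_trail_means[0] == pytest.approx(1.0)

    def test_invariant_to_count_magnitude(self, rng):
        genes = [f"TRBV{i}" for i in range(6)]
        counts = rng.integers(0, 3, size=(8, 6))
        trails = _mk_trails([[f"S{i}" for i in range(4)]])
        sets = _control_sets([[[f"S{i}" for i in range(4, 8)]]])
        r1 = shared_vgene_test(trails, sets, self._ds(counts, genes),
                               ("TRBV",))
        r2 = shared_vgene_test(trails, sets, self._ds(counts * 100, genes),
                               ("TRBV",))
        assert r1.observed_median == r2.observed_median
        assert list(r1.null_medians) == list(r2.null_medians)

    def test_no_matching_genes_lists_prefixes(self):
        ds = self._ds(np.ones((3, 2), dtype=int), ["GENEA", "GENEB"])
        with pytest.raises(ValueError, match="prefixes"):
            shared_vgene_test(_mk_trails([["S0", "S1"]]),
                              _control_sets([[["S1", "S2"]]]), ds, ("TRAV",))


class TestOraFisher:
    def test_disjoint_set_not_enriched(self):
        coll = GeneSetCollection(sets={"S": ("X", "Y")})
        table = ora_fisher(["A", "B"], coll, ["A", "B", "X", "Y", "Z"])
        assert table.loc["S", "overlap"] == 0
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_hypergeometric_tail_oracle(self):
        # table a=3, b=2, c=1, d=14 within a 20-gene universe
        universe = [f"G{i}" for i in range(20)]
        query = universe[:5]                       # a + b = 5
        members = universe[:3] + [universe[5]]     # a = 3, c = 1
        coll = GeneSetCollection(sets={"S": tuple(members)})
        table = ora_fisher(query, coll, universe)
        expected = hypergeom.sf(2, 20, 4, 5)  # P(overlap >= 3)
        assert table.loc["S", "p"] == pytest.approx(expected)

    def test_degenerate_full_overlap(self):
        universe = ["A", "B", "C"]
        coll = GeneSetCollection(sets={"S": ("A", "B", "C")})
        table = ora_fisher(universe, coll, universe)
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_query_outside_universe_errors(self):
        coll = GeneSetCollection(sets={"S": ("A",)})
        with pytest.raises(ValueError):
            ora_fisher(["NOT"], coll, ["A", "B"])


class TestBH:
    def test_matches_hand_rolled_bh(self, rng):
        """bh_adjust agrees with a direct step-up implementation."""
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            got = bh_adjust(p)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            prev = 1.0
            for rank_from_end, idx in enumerate(order[::-1]):
                rank = n - rank_from_end
                prev = min(prev, p[idx] * n / rank)
                adj[idx] = prev
            np.testing.assert_allclose(got, adj, rtol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPhenotypeRank:
    def test_dominant_cluster_gets_top_median_rank(self, rng):
        genes = [f"G{j}" for j in range(10)]
        means = pd.DataFrame(rng.uniform(0, 1, size=(13, 10)),
                             index=[f"C{i}" for i in range(13)],
                             columns=genes)
        means.loc["C5"] = 10.0  # largest mean for every gene
        summary = phenotype_rank(genes, means)
        assert summary.index[0] == "C5"
        assert summary.loc["C5", "median_rank"] == pytest.approx(13.0)

    def test_ranks_match_per_gene_sort_oracle(self, rng):
        means = pd.DataFrame(rng.uniform(0, 5, size=(4, 6)),
                             index=list("wxyz"),
                             columns=[f"G{j}" for j in range(6)])
        summary = phenotype_rank(list(means.columns), means)
        ranks = summary.attrs["ranks"]
        for g in means.columns:
            expected = stats.rankdata(means[g])
            np.testing.assert_allclose(ranks[g].to_numpy(), expected)

    def test_no_overlap_errors(self, rng):
        means = pd.DataFrame(rng.uniform(0, 1, (3, 2)), columns=["A", "B"])
        with pytest.raises(ValueError):
            phenotype_rank(["ZZZ"], means)
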