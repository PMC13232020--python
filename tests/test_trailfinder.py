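import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from remitt.trailfinder import (Trail, build_graph, candidate_endpoints,
                                dijkstra_trail, filter_trails,
                                find_candidate_trails, line3d_collect,
                                line3d_trails, point_segment_distance,
                                rescale_xy_to_z, validate_trail)


def node_table(xy, z, ids=None):
    xy = np.asarray(xy, dtype=float)
    ids = ids or [f"N{i:02d}" for i in range(len(xy))]
    z = np.asarray(z, dtype=float)
    return pd.DataFrame({
        "node_id": ids, "x": xy[:, 0], "y": xy[:, 1], "z": z - z.min(),
        "t_marker_sum": 1.0, "umi_total": 100.0,
        "members": [(i,) for i in ids],
    })


def brute_force_min_path(g, s, e):
    """Exhaustive minimum over all simple directed paths (test oracle)."""
    best = None
    for path in nx.all_simple_paths(g, s, e):
        w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        key = (round(w, 12), len(path), tuple(map(str, path)))
        if best is None or key < best:
            best = key
    return best


class TestBuildGraph:
    def test_adjacent_pair_edge_direction_and_weight(self):
        nodes = node_table([[0, 0], [110, 0]], [0.2, 0.5])
        g = build_graph(nodes)
        assert list(g.edges(data="weight")) == [("N00", "N01", pytest.approx(0.3))]

    def test_distant_pair_has_no_edge(self):
        nodes = node_table([[0, 0], [200, 0]], [0.1, 0.9])
        assert build_graph(nodes).number_of_edges() == 0

    def test_matches_all_pairs_brute_force(self, rng):
        xy = rng.uniform(0, 500, size=(25, 2))
        z = rng.uniform(0, 1, 25)
        nodes = node_table(xy, z)
        g = build_graph(nodes, d_max=130)
        expected = set()
        zs = nodes["z"].to_numpy()
        for i, j in itertools.combinations(range(25), 2):
            if np.linalg.norm(xy[i] - xy[j]) < 130:
                lo, hi = (i, j) if zs[i] <= zs[j] else (j, i)
                expected.add((f"N{lo:02d}", f"N{hi:02d}"))
        assert set(g.edges) == expected

    def test_graph_is_acyclic(self, rng):
        xy = rng.uniform(0, 400, size=(30, 2))
        z = np.round(rng.uniform(0, 1, 30), 1)  # force some ties
        g = build_graph(node_table(xy, z))
        assert nx.is_directed_acyclic_graph(g)

    def test_invalid_d_max(self):
        with pytest.raises(ValueError):
            build_graph(node_table([[0, 0]], [0.0]), d_max=0)


class TestCandidateEndpoints:
    def test_three_nodes_one_start_one_end(self):
        nodes = node_table([[0, 0], [1, 0], [2, 0]], [0.5, 0.1, 0.9])
        starts, ends = candidate_endpoints(nodes)
        assert starts == ["N01"] and ends == ["N02"]

    def test_tercile_sizes_at_n100(self, rng):
        nodes = node_table(rng.uniform(0, 1000, (100, 2)),
                           rng.uniform(0, 1, 100))
        starts, ends = candidate_endpoints(nodes, frac=0.33)
        assert len(starts) == 33 and len(ends) == 33

    def test_membership_matches_sort_oracle(self, rng):
        z = rng.uniform(0, 1, 40)
        nodes = node_table(rng.uniform(0, 1000, (40, 2)), z)
        starts, ends = candidate_endpoints(nodes, frac=0.25)
        order = np.argsort(nodes["z"].to_numpy(), kind="stable")
        assert set(starts) == {f"N{i:02d}" for i in order[:10]}
        assert set(ends) == {f"N{i:02d}" for i in order[-10:]}

    def test_invalid_frac(self, rng):
        nodes = node_table(rng.uniform(0, 9, (5, 2)), rng.uniform(0, 1, 5))
        for frac in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                candidate_endpoints(nodes, frac=frac)


class TestDijkstra:
    def test_increasing_chain_is_returned_whole(self):
        xy = [[i * 100, 0] for i in range(6)]
        nodes = node_table(xy, [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        g = build_graph(nodes)
        trail = dijkstra_trail(g, "N00", "N05")
        assert trail.nodes == tuple(f"N{i:02d}" for i in range(6))
        # telescoping: total weight equals the score difference of endpoints
        total = sum(g[u][v]["weight"]
                    for u, v in zip(trail.nodes, trail.nodes[1:]))
        assert total == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration(self, rng):
        """Dijkstra equals brute force on random small layouts."""
        for _ in range(40):
            n = int(rng.integers(4, 12))
            nodes = node_table(rng.uniform(0, 300, (n, 2)),
                               rng.uniform(0, 1, n))
            g = build_graph(nodes, d_max=160)
            ids = list(g.nodes)
            s, e = ids[0], ids[-1]
            oracle = brute_force_min_path(g, s, e)
            trail = dijkstra_trail(g, s, e)
            if oracle is None:
                assert trail is None
            else:
                w = sum(g[u][v]["weight"]
                        for u, v in zip(trail.nodes, trail.nodes[1:]))
                assert w == pytest.approx(oracle[0], abs=1e-9)

    def test_z_profile_non_decreasing(self, rng):
        for _ in range(10):
            nodes = node_table(rng.uniform(0, 400, (20, 2)),
                               rng.uniform(0, 1, 20))
            g = build_graph(nodes, d_max=200)
            ids = sorted(g.nodes)
            trail = dijkstra_trail(g, ids[0], ids[-1])
            if trail is not None:
                assert all(a <= b + 1e-12 for a, b in
                           zip(trail.z_profile, trail.z_profile[1:]))

    def test_unreachable_returns_none(self):
        nodes = node_table([[0, 0], [1000, 0]], [0.0, 1.0])
        g = build_graph(nodes)
        assert dijkstra_trail(g, "N00", "N01") is None


class TestFilterTrails:
    @staticmethod
    def _trail(n, span):
        return Trail(nodes=tuple(f"N{i}" for i in range(n)),
                     methods=("dijkstra",), span_um=span,
                     z_profile=tuple(range(n)))

    def test_short_trail_removed(self):
        assert filter_trails([self._trail(4, 900)]) == []

    def test_short_span_removed(self):
        assert filter_trails([self._trail(8, 400)]) == []

    def test_matches_predicate_oracle(self, rng):
        trails = [self._trail(int(rng.integers(2, 12)),
                              float(rng.uniform(0, 1200)))
                  for _ in range(50)]
        kept = filter_trails(trails, min_nodes=6, min_span=500)
        assert kept == [t for t in trails
                        if len(t) >= 6 and t.span_um >= 500]


class TestLine3D:
    def test_collinear_nodes_all_collected_in_order(self):
        # 7 nodes on a straight lattice line with linearly increasing z
        xy = [[i * 110, 0] for i in range(7)]
        z = np.linspace(0, 1, 7)
        nodes = node_table(xy, z)
        seq = line3d_collect(nodes, "N00", "N06", dist_cutoff=1e-9)
        assert seq == [f"N{i:02d}" for i in range(7)]

    def test_membership_matches_geometric_oracle(self, rng):
        """Inclusion decided exactly by point-to-segment 3D distance."""
        for _ in range(25):
            n = int(rng.integers(8, 25))
            nodes = node_table(rng.uniform(0, 2000, (n, 2)),
                               rng.uniform(0, 1, n))
            coords = rescale_xy_to_z(nodes)
            ids = list(nodes["node_id"])
            s, e = ids[0], ids[1]
            cutoff = float(rng.uniform(0.05, 0.5))
            seq = line3d_collect(nodes, s, e, cutoff)
            si, ei = 0, 1
            if coords[si, 2] > coords[ei, 2]:
                si, ei = ei, si
            a, b = coords[si], coords[ei]
            expected = []
            for i in range(n):
                d, t = _point_seg_oracle(coords[i], a, b)
                if d <= cutoff:
                    expected.append((t, str(ids[i]), ids[i]))
            assert seq == [x[2] for x in sorted(expected)[:len(expected)]]

    def test_perpendicular_cutoff_boundary(self):
        # segment along x at z in [0, 1]; probe nodes offset in y
        xy = [[0, 0], [1000, 0], [500, 0], [500, 120], [500, 460]]
        nodes = node_table(xy, [0.0, 1.0, 0.5, 0.5, 0.5])
        coords = rescale_xy_to_z(nodes)
        a, b = coords[0], coords[1]
        d_in, _ = _point_seg_oracle(coords[3], a, b)
        d_out, _ = _point_seg_oracle(coords[4], a, b)
        cutoff = 2 * d_in
        assert d_out > cutoff
        seq = line3d_collect(nodes, "N00", "N01", cutoff)
        assert "N03" in seq and "N04" not in seq

    def test_drawback_rejection(self):
        xy = [[i * 110, 0] for i in range(7)]
        z = [0.0, 0.2, 0.4, 0.3, 0.6, 0.8, 1.0]  # dip of 0.1 at index 3
        nodes = node_table(xy, z)
        got = line3d_trails(nodes, ["N00"], ["N06"], dist_cutoff=10.0,
                            min_nodes=3, min_span=500, drawback_tol=0.05)
        assert got == []
        tolerant = line3d_trails(nodes, ["N00"], ["N06"], dist_cutoff=10.0,
                                 min_nodes=3, min_span=500, drawback_tol=0.5)
        assert len(tolerant) == 1

    def test_translation_invariance(self, rng):
        xy = rng.uniform(0, 900, (15, 2))
        z = rng.uniform(0, 1, 15)
        nodes = node_table(xy, z)
        shifted = node_table(xy + 5000.0, z)
        a = line3d_trails(nodes, ["N00"], ["N01"], dist_cutoff=0.2,
                          min_nodes=2, min_span=0, d_max=1e9)
        b = line3d_trails(shifted, ["N00"], ["N01"], dist_cutoff=0.2,
                          min_nodes=2, min_span=0, d_max=1e9)
        assert [t.nodes for t in a] == [t.nodes for t in b]


def _point_seg_oracle(p, a, b):
    """Independent point-to-segment distance by direct formula."""
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    tc = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + tc * ab))), t


class TestFindCandidates:
    def test_no_admissible_pair_gives_empty(self):
        xy = [[i * 100, 0] for i in range(4)]  # span 300 < 500
        nodes = node_table(xy, [0.0, 0.3, 0.6, 1.0])
        g = build_graph(nodes)
        assert find_candidate_trails(g, nodes, min_nodes=3) == []

    def test_planted_monotone_chain_is_found(self):
        xy = [[i * 110, 0] for i in range(8)]
        nodes = node_table(xy, np.linspace(0, 1, 8))
        g = build_graph(nodes)
        cands = find_candidate_trails(g, nodes)
        chains = [t.nodes for t in cands]
        assert tuple(f"N{i:02d}" for i in range(8)) in chains

    def test_duplicate_trail_reported_once_with_both_tags(self):
        xy = [[i * 110, 0] for i in range(8)]
        nodes = node_table(xy, np.linspace(0, 1, 8))
        g = build_graph(nodes)
        cands = find_candidate_trails(g, nodes)
        full = [t for t in cands if len(t) == 8]
        assert len(full) == 1
        assert set(full[0].methods) == {"dijkstra", "line3d"}

    def test_every_candidate_passes_trail_validator(self, sim):
        from remitt.scoring import detect_t_spots, exhaustion_score
        ds, _ = sim
        nodes = exhaustion_score(ds, detect_t_spots(ds))
        g = build_graph(nodes)
        cands = find_candidate_trails(g, nodes)
        assert cands
        for t in cands:
            validate_trail(t, nodes)
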