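import networkx as nx
import numpy as np
import pytest
from scipy.spatial import cKDTree

from skeletrace.errors import ParameterError
from skeletrace.nms import SkeletonCloud, skeletonize
from skeletrace.phantoms import filament_phantom
from skeletrace.seg_graph import (
    Curve,
    build_graph,
    extract_curves,
    spanning_forest,
    split_filaments,
)

from .oracles import brute_force_msf_weight


def _cloud(pts):
    return SkeletonCloud(np.asarray(pts, dtype=float), 1)


class TestBuildGraph:
    def test_collinear_chain(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), epsilon=1.5)
        assert g.n_edges == 2
        assert not g.graph.has_edge(0, 2)

    def test_unit_square_all_pairs(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), epsilon=1.6)
        assert g.n_edges == 6
        lengths = sorted(d["length"] for _, _, d in g.graph.edges(data=True))
        np.testing.assert_allclose(lengths, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])

    def test_strict_inequality_at_epsilon(self):
        g = build_graph(_cloud([[0, 0, 0], [2, 0, 0]]), epsilon=2.0)
        assert g.n_edges == 0

    def test_coincident_points_merged(self):
        g = build_graph(_cloud([[0, 0, 0], [0, 0, 0], [1, 0, 0]]), epsilon=1.5)
        assert g.n_nodes == 2 and g.n_edges == 1

    def test_empty_cloud(self):
        g = build_graph(_cloud(np.empty((0, 3))), epsilon=1.0)
        assert g.n_nodes == 0 and g.n_edges == 0


class TestSpanningForest:
    def test_unit_square_weight(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), epsilon=1.6)
        msf = spanning_forest(g)
        assert msf.n_edges == 3
        assert msf.total_length() == pytest.approx(3.0)

    def test_tree_unchanged(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), epsilon=1.5)
        msf = spanning_forest(g)
        assert sorted(msf.graph.edges) == sorted(g.graph.edges)

    def test_two_triangles(self):
        pts = [[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [10, 0, 0], [11, 0, 0], [10.5, 1, 0]]
        g = build_graph(_cloud(pts), epsilon=1.6)
        msf = spanning_forest(g)
        assert nx.number_connected_components(msf.graph) == 2
        assert msf.n_edges == 4

    def test_matches_bruteforce_on_random_graphs(self):
        # exhaustive minimum spanning forest enumeration on <= 8 nodes
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            pts = rng.random((n, 3)) * 4
            eps = float(rng.uniform(1.0, 4.0))
            g = build_graph(SkeletonCloud(pts, 1), eps)
            edges = [(u, v, d["length"]) for u, v, d in g.graph.edges(data=True)]
            expect = brute_force_msf_weight(list(g.graph.nodes), edges)
            assert spanning_forest(g).total_length() == pytest.approx(expect)

    def test_acyclic_output(self):
        rng = np.random.default_rng(3)
        g = build_graph(SkeletonCloud(rng.random((40, 3)) * 5, 1), 2.0)
        msf = spanning_forest(g)
        assert nx.is_forest(msf.graph)
        assert msf.n_edges == msf.n_nodes - nx.number_connected_components(msf.graph)


class TestSplitFilaments:
    def test_y_junction(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0]]), epsilon=1.5)
        out = split_filaments(spanning_forest(g))
        comps = sorted(len(c) for c in nx.connected_components(out.graph))
        assert comps == [2, 3]
        assert out.max_degree() <= 2

    def test_simple_path_unchanged(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), epsilon=1.5)
        out = split_filaments(g)
        assert sorted(out.graph.edges) == sorted(g.graph.edges)

    def test_x_junction_tiebreak(self):
        # two 180-degree pairs; the first in edge order survives intact
        g = build_graph(
            _cloud([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]), epsilon=1.2
        )
        out = split_filaments(g)
        assert nx.number_connected_components(out.graph) == 3
        assert out.n_nodes == 7 and out.n_edges == 4
        comp_of_center = nx.node_connected_component(out.graph, 0)
        assert comp_of_center == {0, 1, 2}  # the +-x pair came first

    def test_edge_count_conserved_and_duplicate_count(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pts = rng.random((30, 3)) * 6
            g = spanning_forest(build_graph(SkeletonCloud(pts, 1), 2.5))
            excess = sum(max(0, d - 2) for _, d in g.graph.degree)
            out = split_filaments(g)
            assert out.n_edges == g.n_edges
            assert out.n_nodes == g.n_nodes + excess
            assert out.max_degree() <= 2
            assert nx.number_connected_components(out.graph) == (
                nx.number_connected_components(g.graph) + excess
            )

    def test_cyclic_input_rejected(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [0.5, 1, 0]]), epsilon=1.6)
        with pytest.raises(ParameterError):
            split_filaments(g)


class TestExtractCurves:
    def test_five_node_path_ordering(self):
        pts = [[4, 0, 0], [3, 0, 0], [2, 0, 0], [1, 0, 0], [0, 0, 0]]
        g = build_graph(_cloud(pts), epsilon=1.5)
        curves = extract_curves(g)
        assert len(curves) == 1
        np.testing.assert_array_equal(curves[0].points[0], [0, 0, 0])
        np.testing.assert_array_equal(curves[0].points[-1], [4, 0, 0])

    def test_min_length_boundary(self):
        def chain(n, vs):
            pts = np.zeros((n + 1, 3))
            pts[:, 0] = np.arange(n + 1)
            g = build_graph(SkeletonCloud(pts, 1, voxel_size=vs), epsilon=1.5)
            g.voxel_size = vs
            return g

        # 84 nm removed, 86 nm retained at an 85 nm cutoff
        assert extract_curves(chain(84, 1.0), min_length=85.0) == []
        assert len(extract_curves(chain(86, 1.0), min_length=85.0)) == 1

    def test_split_y_yields_two_curves(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0]]), epsilon=1.5)
        curves = extract_curves(split_filaments(spanning_forest(g)))
        assert sorted(len(c) for c in curves) == [2, 3]

    def test_degree_over_two_rejected(self):
        g = build_graph(_cloud([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0]]), epsilon=1.5)
        with pytest.raises(ParameterError):
            extract_curves(spanning_forest(g))


class TestEndToEndTubes:
    def test_disjoint_tubes_recovered_exactly(self):
        # three spanning straight tubes; the full trace pipeline must return
        # exactly three curves lying on the true centerlines
        for seed in (5, 7, 11):
            seg, truth = filament_phantom(
                shape=96, kind="straight", tube_radius=4,
                params={"n_filaments": 3, "min_separation": 20}, seed=seed,
            )
            cloud = skeletonize(seg, 1, threshold=1.5, spacing=6.0)
            g = split_filaments(spanning_forest(build_graph(cloud, 9.0)))
            curves = extract_curves(g, min_length=20.0)
            assert len(curves) == 3
            gt = cKDTree(truth.gt_points)
            for c in curves:
                assert gt.query(c.points)[0].max() < 1.5
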