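import networkx as nx
import numpy as np
import pytest

from skeletrace.curve_geometry import persistence_length
from skeletrace.errors import PackingError, ParameterError
from skeletrace.phantoms import (
    blob_phantom,
    dilate,
    filament_phantom,
    membrane_phantom,
    wormlike_chain,
)
from skeletrace.seg_graph import Curve
from skeletrace.seg_metrics import skeleton_precision
from skeletrace.nms import SkeletonCloud


class TestMembranePhantom:
    def test_single_shell_volume_analytic(self):
        seg, truth = membrane_phantom(shape=128, n_shells=1, radius_range=(30, 30),
                                      thickness_range=(5, 5), seed=0)
        (c, R, t) = truth.params["shells"][0]
        expected = 4 * np.pi * R**2 * t
        assert seg.data.sum() == pytest.approx(expected, rel=0.05)

    def test_gt_points_on_midsurface(self):
        seg, truth = membrane_phantom(shape=96, n_shells=2, radius_range=(14, 20), seed=1)
        # every gt point sits on the mid-sphere of its nearest shell
        centers = np.array([c for c, _, _ in truth.params["shells"]])
        radii = np.array([R for _, R, _ in truth.params["shells"]])
        d = np.linalg.norm(truth.gt_points[:, None, :] - centers[None], axis=2)
        nearest = d.argmin(axis=1)
        radial = d[np.arange(len(d)), nearest]
        assert np.abs(radial - radii[nearest]).max() < 0.51
        # and inside the segmentation foreground
        idx = np.rint(truth.gt_points).astype(int)
        assert (seg.data[idx[:, 0], idx[:, 1], idx[:, 2]] == 1).all()

    def test_deterministic(self):
        a, _ = membrane_phantom(shape=64, n_shells=1, radius_range=(15, 20), seed=7)
        b, _ = membrane_phantom(shape=64, n_shells=1, radius_range=(15, 20), seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_thin_shell_rejected(self):
        with pytest.raises(ParameterError):
            membrane_phantom(thickness_range=(2, 2), seed=0)

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            membrane_phantom(shape=64, n_shells=10, radius_range=(25, 30), seed=0)


class TestFilamentPhantom:
    def test_straight_tube_cross_section(self):
        seg, truth = filament_phantom(shape=64, kind="straight", tube_radius=4,
                                      params={"n_filaments": 1}, seed=3)
        # voxel count ~ length * pi r^2
        length = sum(
            np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            for p in [truth.gt_points]
        )
        assert seg.data.sum() == pytest.approx(np.pi * 16 * length, rel=0.15)

    def test_branched_graph_has_branch_node(self):
        _, truth = filament_phantom(shape=96, kind="branched", seed=2,
                                    params={"n_branches": 1})
        degrees = [d for _, d in truth.gt_graph.degree]
        assert max(degrees) == 3
        assert nx.is_tree(truth.gt_graph)

    def test_gt_points_inside_foreground(self):
        for kind in ("straight", "helix", "wormlike", "branched"):
            seg, truth = filament_phantom(shape=96, kind=kind, seed=4)
            idx = np.rint(truth.gt_points).astype(int)
            idx = np.clip(idx, 0, 95)
            assert (seg.data[idx[:, 0], idx[:, 1], idx[:, 2]] == 1).all(), kind

    def test_gt_skeleton_scores_perfect_precision(self):
        seg, truth = filament_phantom(shape=96, kind="wormlike", seed=5)
        cloud = SkeletonCloud(np.clip(truth.gt_points, 0, 95), 1)
        assert skeleton_precision(cloud, seg).precision == 1.0

    def test_deterministic(self):
        a, _ = filament_phantom(shape=64, kind="wormlike", seed=6)
        b, _ = filament_phantom(shape=64, kind="wormlike", seed=6)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            filament_phantom(kind="zigzag", seed=0)

    def test_wormlike_centerline_recovers_lp(self):
        # truncated chains keep free wormlike statistics, so the pooled
        # tangent-correlation fit over many phantoms recovers the stiffness
        curves = []
        for seed in range(20):
            _, truth = filament_phantom(
                shape=128, kind="wormlike", seed=seed,
                params={"persistence_length": 100.0, "n_segments": 150},
            )
            curves.append(Curve(truth.gt_points))
        assert persistence_length(curves) == pytest.approx(100.0, rel=0.20)


class TestBlobPhantom:
    def test_count_and_separation(self):
        _, truth = blob_phantom(shape=128, n_blobs=20, radius=5, min_separation=20, seed=0)
        assert len(truth.gt_centers) == 20
        from scipy.spatial.distance import pdist

        assert pdist(truth.gt_centers).min() >= 20

    def test_foreground_volume_analytic(self):
        seg, _ = blob_phantom(shape=128, n_blobs=20, radius=5, min_separation=20, seed=1)
        assert seg.data.sum() == pytest.approx(20 * 4 / 3 * np.pi * 125, rel=0.05)

    def test_deterministic(self):
        a, ta = blob_phantom(shape=64, n_blobs=5, radius=4, min_separation=15, seed=2)
        b, tb = blob_phantom(shape=64, n_blobs=5, radius=4, min_separation=15, seed=2)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta.gt_centers, tb.gt_centers)

    def test_packing_failure(self):
        with pytest.raises(PackingError):
            blob_phantom(shape=48, n_blobs=100, radius=5, min_separation=30, seed=0)


class TestDilate:
    def test_single_voxel_six_neighbors(self):
        from skeletrace.volume_io import BinaryVolume

        v = np.zeros((7, 7, 7), np.uint8)
        v[3, 3, 3] = 1
        out = dilate(BinaryVolume(v), 1)
        assert out.data.sum() == 7

    def test_zero_iterations_identity(self, small_shell):
        out = dilate(small_shell, 0)
        np.testing.assert_array_equal(out.data, small_shell.data)

    def test_monotone_growth(self, small_shell):
        counts = [dilate(small_shell, k).data.sum() for k in range(4)]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_26_connectivity_grows_faster(self, small_shell):
        assert dilate(small_shell, 1, connectivity=3).data.sum() > dilate(small_shell, 1).data.sum()


class TestWormlikeChain:
    def test_tangent_correlation_decay(self):
        rng = np.random.default_rng(0)
        # mean cosine between successive unit tangents ~ exp(-1/lp)
        chains = [wormlike_chain(300, 50.0, rng) for _ in range(20)]
        cosines = []
        for pts in chains:
            t = np.diff(pts, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            cosines.append(np.einsum("ij,ij->i", t[:-1], t[1:]).mean())
        assert np.mean(cosines) == pytest.approx(np.exp(-1 / 50.0), abs=0.01)

    def test_unit_steps(self):
        rng = np.random.default_rng(1)
        pts = wormlike_chain(50, 100.0, rng)
        np.testing.assert_allclose(np.linalg.norm(np.diff(pts, axis=0), axis=1), 1.0)

    def test_bounded_walk_stays_inside(self):
        rng = np.random.default_rng(2)
        pts = wormlike_chain(500, 200.0, rng, start=(32, 32, 32),
                             bounds=(64, 64, 64), margin=4.0)
        assert pts.min() >= 0 and pts.max() <= 63
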