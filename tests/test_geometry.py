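import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantstress3d.geometry import (
    CameraModel,
    Leaf3D,
    back_project,
    code_to_depth,
    depth_to_code,
    forward_project,
    leaf_centroid,
    leaf_moments,
    pixel_to_image_plane,
    reconstruct_leaf,
    rms_error,
    write_centroids_csv,
    write_ply,
)

CAM = CameraModel(
    focal_length=100.0, principal_point=(50.0, 50.0), max_depth=4.0, image_size=(101, 101)
)


class TestCodeToDepth:
    def test_worked_example_half_code(self):
        # k = 4 m, z = 128 -> approximately 2 m
        assert code_to_depth(128, 4.0) == pytest.approx(2.0078, abs=1e-4)
        assert round(code_to_depth(128, 4.0)) == 2

    def test_endpoints(self):
        assert code_to_depth(0, 4.0) == 0.0
        assert code_to_depth(255, 4.0) == 4.0

    def test_monotone_in_code(self):
        z = np.arange(256)
        Z = code_to_depth(z, 4.0)
        assert np.all(np.diff(Z) > 0)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            code_to_depth(256, 4.0)
        with pytest.raises(ValueError):
            code_to_depth(-1, 4.0)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            code_to_depth(10, 0.0)

    def test_inverse_roundtrip(self):
        for z in (0, 1, 54, 128, 255):
            assert depth_to_code(code_to_depth(z, 4.0), 4.0) == z


class TestBackProject:
    def test_principal_point_on_axis(self):
        X, Y, Z = back_project(0.0, 0.0, 1.7, CAM)
        assert X == 0.0 and Y == 0.0 and Z == 1.7

    def test_unit_slope_ray(self):
        X, _, _ = back_project(CAM.focal_length, 0.0, 2.0, CAM)
        assert X == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None)
    @given(
        X=st.floats(-2, 2),
        Y=st.floats(-2, 2),
        Z=st.floats(0.1, 4.0),
    )
    def test_forward_backward_roundtrip(self, X, Y, Z):
        x, y = forward_project(X, Y, Z, CAM)
        Xb, Yb, Zb = back_project(x, y, Z, CAM)
        assert Xb == pytest.approx(X, abs=1e-9)
        assert Yb == pytest.approx(Y, abs=1e-9)
        assert Zb == Z

    def test_bad_focal_length_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(focal_length=0.0)


class TestReconstructLeaf:
    def test_single_pixel_at_principal_point_max_code(self):
        depth = np.zeros((101, 101), np.uint8)
        depth[50, 50] = 255
        leaf = reconstruct_leaf(np.array([[50, 50]]), depth, CAM)
        assert leaf.w == 1
        np.testing.assert_allclose(leaf.points[0], [0.0, 0.0, 4.0])

    def test_point_count_matches_region(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 256, (101, 101)).astype(np.uint8)
        mask = rng.random((101, 101)) < 0.1
        leaf = reconstruct_leaf(mask, depth, CAM)
        assert leaf.w == int(mask.sum())

    def test_constant_depth_region_is_coplanar(self):
        depth = np.full((101, 101), 100, np.uint8)
        mask = np.zeros((101, 101), bool)
        mask[40:60, 30:70] = True
        leaf = reconstruct_leaf(mask, depth, CAM)
        # plane-fit residual for Z = const is exactly zero
        assert np.ptp(leaf.points[:, 2]) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_leaf(np.zeros((101, 101), bool), np.zeros((101, 101)), CAM)

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            reconstruct_leaf(np.array([[500, 2]]), np.zeros((101, 101)), CAM)


class TestMoments:
    POINTS = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])

    def test_zeroth_moment_is_count(self):
        pts = np.arange(21).reshape(7, 3).astype(float)
        assert leaf_moments(pts, 0, 0, 0) == 7.0

    def test_first_moments_direct_sum(self):
        assert leaf_moments(self.POINTS, 1, 0, 0) == 4.0
        assert leaf_moments(self.POINTS, 0, 1, 0) == 6.0
        assert leaf_moments(self.POINTS, 0, 0, 1) == 8.0

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (23, 3))
        for p in (0, 1):
            for q in (0, 1):
                for g in (0, 1):
                    oracle = sum(x**p * y**q * z**g for x, y, z in pts)
                    assert leaf_moments(pts, p, q, g) == pytest.approx(oracle)

    def test_translation_adds_w_times_t(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (9, 3))
        t = 0.75
        before = leaf_moments(pts, 1, 0, 0)
        after = leaf_moments(pts + np.array([t, 0, 0]), 1, 0, 0)
        assert after == pytest.approx(before + 9 * t)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            leaf_moments(self.POINTS, 2, 0, 0)


class TestCentroid:
    def test_mean_oracle(self):
        c = leaf_centroid(TestMoments.POINTS)
        np.testing.assert_allclose(c, [2.0, 3.0, 4.0])

    def test_single_point_identity(self):
        c = leaf_centroid(np.array([[0.4, -0.2, 1.1]]))
        np.testing.assert_allclose(c, [0.4, -0.2, 1.1])

    @settings(max_examples=25, deadline=None)
    @given(
        t=st.tuples(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3)),
        seed=st.integers(0, 100),
    )
    def test_translation_equivariance(self, t, seed):
        pts = np.random.default_rng(seed).normal(0, 1, (6, 3))
        shift = np.array(t)
        np.testing.assert_allclose(
            leaf_centroid(pts + shift), leaf_centroid(pts) + shift, atol=1e-9
        )

    def test_centroid_inside_bounding_box(self):
        pts = np.random.default_rng(3).normal(0, 1, (17, 3))
        leaf = Leaf3D(pts)
        assert np.all(leaf.centroid >= pts.min(axis=0))
        assert np.all(leaf.centroid <= pts.max(axis=0))


class TestRMS:
    def test_zero_when_identical(self):
        pts = np.random.default_rng(4).normal(0, 1, (5, 3))
        res = rms_error(pts, pts)
        np.testing.assert_allclose(res.per_axis, 0.0)
        assert res.average == 0.0

    def test_reported_average_from_components(self):
        # per-axis RMS components printed for the proposed 3D model
        per_axis = np.array([0.009217, 0.008913, 0.069241])
        assert round(float(per_axis.mean()), 6) == 0.029124

    def test_single_pair_closed_form(self):
        pred = np.array([[0.0, 0.0, 0.0]])
        gt = np.array([[0.3, 0.0, 0.4]])
        res = rms_error(pred, gt)
        np.testing.assert_allclose(res.per_axis, [0.3, 0.0, 0.4])

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(0, 1, (8, 3))
        gt = pred + rng.normal(0, 0.01, (8, 3))
        perm = rng.permutation(8)
        a = rms_error(pred, gt)
        b = rms_error(pred[perm], gt[perm])
        np.testing.assert_allclose(a.per_axis, b.per_axis)

    def test_nearest_matching_recovers_permuted_pairs(self):
        rng = np.random.default_rng(6)
        gt = rng.uniform(-1, 1, (6, 3))
        pred = gt + rng.normal(0, 1e-4, (6, 3))
        res = rms_error(pred, gt[rng.permutation(6)], matching="nearest")
        assert res.n_matched == 6
        assert res.average < 1e-3

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            rms_error(
                np.array([[0, 0, 0.0]]),
                np.array([[5, 5, 0.0]]),
                matching="nearest",
                gate=0.1,
            )


class TestExports:
    def test_ply_and_csv(self, tmp_path):
        depth = np.full((101, 101), 64, np.uint8)
        mask = np.zeros((101, 101), bool)
        mask[10:14, 10:14] = True
        leaf = reconstruct_leaf(mask, depth, CAM, superpixel_id=3)
        ply = tmp_path / "cloud.ply"
        write_ply(ply, [leaf])
        lines = ply.read_text().splitlines()
        assert lines[0] == "ply"
        assert f"element vertex {leaf.w}" in lines
        assert lines[-1].endswith(" 3")
        csv_path = tmp_path / "centroids.csv"
        write_centroids_csv(csv_path, [leaf])
        assert csv_path.read_text().splitlines()[0] == "leaf_id,X,Y,Z"
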