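import numpy as np
import pytest

from barntrack import (CameraModel, ConvergenceError, GeometryError,
                       GroundDetection, PlaneHomography, estimate_homography,
                       fuse_overlap_detections, project_detections,
                       undistort_points)
from barntrack.geometry import distort_points


@pytest.fixture
def cam():
    return CameraModel(focal=(700.0, 700.0), principal_point=(400.0, 300.0),
                       distortion=(-0.1, 0.02), image_size=(800, 600))


class TestUndistortion:
    def test_zero_distortion_is_identity(self):
        cam = CameraModel((700, 700), (400, 300), (0.0, 0.0))
        pts = np.array([[100.0, 50.0], [400.0, 300.0], [750.0, 580.0]])
        out = undistort_points(pts, cam)
        expected = (pts - [400, 300]) / 700.0
        assert np.allclose(out, expected, atol=1e-12)

    def test_forward_backward_round_trip(self, cam):
        rng = np.random.default_rng(1)
        pts_n = rng.uniform(-0.45, 0.45, size=(50, 2))
        back = undistort_points(distort_points(pts_n, cam), cam)
        assert np.abs(back - pts_n).max() < 1e-8

    def test_principal_point_is_fixed(self, cam):
        out = undistort_points(np.array([[400.0, 300.0]]), cam)
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_absurd_coefficients_fail_loudly(self):
        cam = CameraModel((700, 700), (400, 300), (-5.0, 8.0))
        with pytest.raises(ConvergenceError):
            undistort_points(np.array([[750.0, 580.0]]), cam)


class TestHomographyEstimation:
    def test_unit_square_identity(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        H, rms = estimate_homography(pts, pts)
        assert np.allclose(H.matrix, np.eye(3), atol=1e-10)
        assert rms < 1e-10

    def test_known_homography_recovered(self):
        rng = np.random.default_rng(7)
        Ht = np.array([[0.9, -0.2, 120.0], [0.15, 1.1, -40.0],
                       [1e-4, -2e-4, 1.0]])
        src = rng.uniform(0, 800, size=(6, 2))
        h = np.hstack([src, np.ones((6, 1))]) @ Ht.T
        dst = h[:, :2] / h[:, 2:]
        H, rms = estimate_homography(src, dst)
        assert rms < 1e-8
        assert np.allclose(H.matrix, Ht, atol=1e-8)

    def test_collinear_points_raise(self):
        src = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(GeometryError):
            estimate_homography(src, src)

    def test_too_few_points_raise(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            estimate_homography(pts, pts)

    def test_round_trip_with_inverse(self):
        Ht = np.array([[0.9, -0.2, 12.0], [0.15, 1.1, -4.0], [1e-3, 2e-3, 1.0]])
        H = PlaneHomography(Ht)
        pts = np.random.default_rng(0).uniform(-5, 5, size=(40, 2))
        back = H.inverse().apply(H.apply(pts))
        assert np.abs(back - pts).max() < 1e-9


class TestProjection:
    def test_identity_camera_and_plane(self):
        cam = CameraModel((1.0, 1.0), (0.0, 0.0), (0.0, 0.0))
        H = PlaneHomography(np.eye(3))
        dets = project_detections([[2.0, 3.0]], [0], [0.8], cam, H,
                                  n_orient=8, camera_id="c")
        assert dets[0].world_xy == pytest.approx((2.0, 3.0))
        assert dets[0].orient_bin == 0
        assert dets[0].weight == 0.8

    def test_pure_translation_shifts_everything(self):
        cam = CameraModel((1.0, 1.0), (0.0, 0.0))
        T = np.eye(3)
        T[0, 2], T[1, 2] = 5.0, -2.0
        H = PlaneHomography(T)
        dets = project_detections([[0.0, 0.0], [1.0, 1.0]], [2, 5], [1, 1],
                                  cam, H, n_orient=8)
        assert dets[0].world_xy == pytest.approx((5.0, -2.0))
        assert dets[1].world_xy == pytest.approx((6.0, -1.0))
        assert [d.orient_bin for d in dets] == [2, 5]   # translation keeps angles

    def test_rotation_rotates_orientation_bins(self):
        cam = CameraModel((1.0, 1.0), (0.0, 0.0))
        a = np.pi / 2
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        dets = project_detections([[1.0, 0.0]], [0], [1.0], cam,
                                  PlaneHomography(R), n_orient=8)
        assert dets[0].orient_bin == 2                   # +x becomes +y

    def test_synthetic_cow_recovered_through_full_chain(self, cam):
        """Forward-render a world point through homography + distortion and
        recover it to within 1e-6 m."""
        Ht = np.array([[0.02, 0.001, -4.0], [-0.002, 0.021, -3.0],
                       [1e-5, -1e-5, 1.0]])    # pixels -> meters on the plane
        H = PlaneHomography(Ht)
        world = np.array([3.2, 11.5])
        ideal_px = H.inverse().apply(world)[0]
        norm = (ideal_px - np.array(cam.principal_point)) / np.array(cam.focal)
        distorted_px = distort_points(norm[None, :], cam)
        dets = project_detections(distorted_px, [3], [0.9], cam, H, n_orient=8)
        assert np.abs(np.array(dets[0].world_xy) - world).max() < 1e-6


class TestFusion:
    def test_two_camera_pair_merges_to_weighted_centroid(self):
        a = GroundDetection("cam1", (1.00, 2.00), 4, 0.6)
        b = GroundDetection("cam2", (1.12, 2.00), 4, 0.9)
        (f,) = fuse_overlap_detections([a, b], merge_radius_m=0.5, n_orient=32)
        cx = (0.6 * 1.00 + 0.9 * 1.12) / 1.5
        assert f.world_xy[0] == pytest.approx(cx)
        assert f.weight == 0.9
        assert f.orient_bin == 4

    def test_distant_cows_stay_separate(self):
        a = GroundDetection("cam1", (1.0, 2.0), 4, 0.8)
        b = GroundDetection("cam2", (4.0, 2.0), 4, 0.8)
        assert len(fuse_overlap_detections([a, b], 0.5)) == 2

    def test_orientation_gating(self):
        a = GroundDetection("cam1", (1.0, 2.0), 0, 0.8)
        b = GroundDetection("cam2", (1.1, 2.0), 8, 0.8)   # 8 bins apart of 32
        assert len(fuse_overlap_detections([a, b], 0.5, n_orient=32)) == 2

    def test_single_camera_unchanged(self):
        dets = [GroundDetection("cam1", (1.0, 2.0), 0, 0.8),
                GroundDetection("cam1", (1.1, 2.0), 0, 0.7)]
        assert fuse_overlap_detections(dets, 0.5) == dets

    def test_three_camera_stitch_gives_one_detection_per_cow(self):
        """Three overlapping views of a 6 x 18 m plane: every cow seen by
        one, two or three cameras fuses to a single consistent detection."""
        rng = np.random.default_rng(5)
        cows = [(1.0, 2.5), (3.0, 6.0), (5.2, 11.5), (2.2, 15.0)]
        views = {"cam1": (0.0, 7.0), "cam2": (5.5, 12.5), "cam3": (11.0, 18.0)}
        dets = []
        for cam_id, (y0, y1) in sorted(views.items()):
            for i, (x, y) in enumerate(cows):
                if y0 <= y <= y1:
                    jitter = rng.normal(0, 0.02, 2)
                    dets.append(GroundDetection(
                        cam_id, (x + jitter[0], y + jitter[1]), i % 32, 0.9))
        assert len(dets) > len(cows)            # overlaps produce duplicates
        fused = fuse_overlap_detections(dets, merge_radius_m=0.5, n_orient=32)
        assert len(fused) == len(cows)
        for f in fused:
            assert f.weight <= 1.0
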