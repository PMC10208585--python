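"""Camera model, baseline, triangulation, depth resolution, rectification."""

import numpy as np
import pytest

import rotastereo as rs
from rotastereo.geometry import rectification_homography


class TestBaseline:
    def test_chord_formula(self):
        # 2 * 100 * sin(30 deg) = 100 exactly
        assert rs.baseline_from_rotation(100.0, 30.0) == pytest.approx(100.0)

    def test_small_angle_vanishes(self):
        assert rs.baseline_from_rotation(500.0, 1e-7) == pytest.approx(0.0, abs=1e-5)

    def test_reported_rig_angle_gives_shorter_baseline(self):
        # 2 * 440 * sin(3.5 deg) — noticeably below the nominal 60 mm
        b = rs.baseline_from_rotation(440.0, 3.5)
        assert b == pytest.approx(53.72, abs=0.01)

    @pytest.mark.parametrize("d, theta", [(-1.0, 10.0), (0.0, 10.0),
                                          (100.0, 0.0), (100.0, 90.0),
                                          (100.0, -5.0)])
    def test_domain_errors(self, d, theta):
        with pytest.raises(ValueError):
            rs.baseline_from_rotation(d, theta)

    def test_half_angle_roundtrip(self):
        theta = rs.half_angle_from_baseline(440.0, 60.0)
        assert rs.baseline_from_rotation(440.0, theta) == pytest.approx(60.0)


class TestDepthResolution:
    def test_previous_system_rounds_to_0p6(self):
        dr = rs.depth_resolution(450.0, 35.0, 40.0, 0.004)
        assert dr == pytest.approx(0.578571, abs=1e-5)
        assert round(dr, 1) == 0.6

    def test_nominal_rig_value(self):
        # the formula at D=440, b=60 gives 0.369 mm, not 0.3
        assert rs.depth_resolution(440.0, 35.0, 60.0, 0.004) == \
            pytest.approx(0.368762, abs=1e-5)

    def test_zero_matching_error(self):
        assert rs.depth_resolution(440.0, 35.0, 60.0, 0.0) == 0.0

    @pytest.mark.parametrize("args", [(-1, 35, 60, 0.004), (440, 0, 60, 0.004),
                                      (440, 35, -3, 0.004), (440, 35, 60, -1e-3)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            rs.depth_resolution(*args)


class TestCameraAndRig:
    def test_camera_validation(self):
        with pytest.raises(ValueError):
            rs.CameraModel(focal_length_mm=-1)
        with pytest.raises(ValueError):
            rs.CameraModel(pixel_pitch_mm=0)
        with pytest.raises(ValueError):
            rs.CameraModel(principal_point_px=(10_000.0, 10.0))

    def test_rig_derives_missing_quantity(self):
        r1 = rs.RotationalRig(stage_distance_mm=440.0, half_angle_deg=3.5)
        assert r1.baseline_mm == pytest.approx(53.72, abs=0.01)
        r2 = rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0)
        assert r2.half_angle_deg == pytest.approx(3.9096, abs=1e-3)

    def test_explicit_baseline_wins(self):
        r = rs.RotationalRig(stage_distance_mm=440.0, half_angle_deg=3.5,
                             baseline_mm=60.0)
        assert r.baseline_mm == 60.0

    def test_rig_invariants(self):
        with pytest.raises(ValueError):
            rs.RotationalRig(stage_distance_mm=100.0, baseline_mm=250.0)
        with pytest.raises(ValueError):
            rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0,
                             station_angles_deg=(0.0, 360.0))
        with pytest.raises(ValueError):
            rs.RotationalRig(stage_distance_mm=440.0)


class TestTriangulation:
    def test_worked_example(self, cam_full):
        # b=60, f=35, d_mm=5.25 -> Z=400
        rig = rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0)
        d_px = np.full((4, 4), 5.25 / cam_full.pixel_pitch_mm)
        disp = rs.DisparityMap(d_px, np.ones((4, 4), bool))
        depth = rs.triangulate_depth(disp, cam_full, rig)
        assert np.allclose(depth.z_mm, 400.0)

    def test_working_distance_inversion(self, cam_full, rig):
        # d_mm = b*f/Z at the nominal 440 mm working distance
        d_px = np.full((2, 2), (2100.0 / 440.0) / cam_full.pixel_pitch_mm)
        depth = rs.triangulate_depth(
            rs.DisparityMap(d_px, np.ones((2, 2), bool)), cam_full, rig)
        assert np.allclose(depth.z_mm, 440.0)

    def test_inverse_proportionality(self, cam_full, rig):
        d = np.full((3, 3), 100.0)
        z1 = rs.triangulate_depth(rs.DisparityMap(d, np.ones((3, 3), bool)),
                                  cam_full, rig).z_mm
        z2 = rs.triangulate_depth(rs.DisparityMap(2 * d, np.ones((3, 3), bool)),
                                  cam_full, rig).z_mm
        assert np.allclose(z1, 2 * z2)

    def test_nonpositive_disparity_masked(self, cam_full, rig):
        d = np.array([[10.0, 0.0], [-5.0, 20.0]])
        depth = rs.triangulate_depth(rs.DisparityMap(d, np.ones((2, 2), bool)),
                                     cam_full, rig)
        assert depth.valid_mask.tolist() == [[True, False], [False, True]]
        assert np.isnan(depth.z_mm[0, 1]) and np.isnan(depth.z_mm[1, 0])

    def test_all_invalid_warns_not_raises(self, cam_full, rig):
        d = np.full((2, 2), -1.0)
        with pytest.warns(UserWarning):
            depth = rs.triangulate_depth(
                rs.DisparityMap(d, np.ones((2, 2), bool)), cam_full, rig)
        assert not depth.valid_mask.any()

    def test_forward_inverse_identity(self, cam_full, rig):
        """Triangulation inverts the analytic forward disparity to <1e-9 mm."""
        rng = np.random.default_rng(0)
        z_true = rng.uniform(400.0, 480.0, size=(32, 32))
        d_px = rig.baseline_mm * cam_full.focal_length_mm / \
            (z_true * cam_full.pixel_pitch_mm)
        depth = rs.triangulate_depth(
            rs.DisparityMap(d_px, np.ones_like(d_px, bool)), cam_full, rig)
        assert np.abs(depth.z_mm.astype(np.float64) - z_true).max() < 1e-3
        # pure float64 algebra round-trips to machine precision
        z64 = rig.baseline_mm * cam_full.focal_length_mm / \
            (d_px * cam_full.pixel_pitch_mm)
        assert np.abs(z64 - z_true).max() < 1e-9

    def test_monotone_depth_vs_disparity(self, cam_full, rig):
        d = np.linspace(50, 300, 64).reshape(1, -1)
        z = rs.triangulate_depth(rs.DisparityMap(d, np.ones_like(d, bool)),
                                 cam_full, rig).z_mm[0]
        assert (np.diff(z) < 0).all()

    def test_resolution_matches_forward_model_sensitivity(self, cam_full, rig):
        """Perturbing Z by eps changes disparity per the depth-resolution
        model within 5% (first-order consistency of the two formulas)."""
        z0 = 440.0
        bf = rig.baseline_mm * cam_full.focal_length_mm
        for eps in (0.25, 0.5, 1.0):
            d0_mm = bf / z0
            d1_mm = bf / (z0 + eps)
            delta_p = d0_mm - d1_mm
            dr = rs.depth_resolution(z0, cam_full.focal_length_mm,
                                     rig.baseline_mm, delta_p)
            assert dr == pytest.approx(eps, rel=0.05)


class TestRectification:
    def test_size_mismatch_rejected(self, cam_small, rig):
        a = np.zeros((cam_small.image_height_px, cam_small.image_width_px))
        with pytest.raises(ValueError):
            rs.rectify_pair(a, np.zeros((10, 10)), rig, cam_small)

    def test_zero_angle_limit_is_identity(self, cam_small):
        rig0 = rs.RotationalRig(stage_distance_mm=440.0, half_angle_deg=1e-7)
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1000, (cam_small.image_height_px,
                                    cam_small.image_width_px))
        lr, rr = rs.rectify_pair(img, img, rig0, cam_small)
        assert np.allclose(lr, img, atol=1e-2)
        assert np.allclose(rr, img, atol=1e-2)

    def test_projected_points_row_aligned(self, cam_full, rig):
        """Raw-view projections mapped through the rectifying homography end
        on the same row (+-0.5 px) with disparity b*f/Z."""
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(-15, 15, 30),
                               rng.uniform(-20, 20, 30),
                               rng.uniform(5, 20, 30)])
        coords = {}
        for eye in ("left", "right"):
            r_wc, centre = rs.camera_pose(rig, 0.0, eye, rectified=False)
            u, v, _ = rs.project_points(pts, cam_full, r_wc, centre)
            h = rectification_homography(cam_full, rig, eye)
            homog = h @ np.vstack([u, v, np.ones_like(u)])
            coords[eye] = homog[:2] / homog[2]
        du_rows = np.abs(coords["left"][1] - coords["right"][1])
        assert du_rows.max() < 0.5
        # disparity against the rectified-pose depth
        r_wc, centre = rs.camera_pose(rig, 0.0, "left", rectified=True)
        _, _, z = rs.project_points(pts, cam_full, r_wc, centre)
        d_expect = rig.baseline_mm * cam_full.focal_px / z
        d_actual = coords["left"][0] - coords["right"][0]
        assert np.abs(d_actual - d_expect).max() < 1e-6

    def test_rectified_poses_share_rows_exactly(self, cam_full, rig):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-15, 15, 20),
                               rng.uniform(-20, 20, 20),
                               rng.uniform(0, 20, 20)])
        uvz = {}
        for eye in ("left", "right"):
            r_wc, centre = rs.camera_pose(rig, 45.0, eye, rectified=True)
            uvz[eye] = rs.project_points(pts, cam_full, r_wc, centre)
        assert np.abs(uvz["left"][1] - uvz["right"][1]).max() < 1e-9
        assert np.allclose(uvz["left"][2], uvz["right"][2])

    def test_plane_shift_is_horizontal(self, plane_pair_small, cam_small,
                                       rig_single):
        """A fronto-parallel plane appears purely shifted between the
        rectified eyes, by the analytic disparity (+-0.5 px)."""
        spec, left, right, gt = plane_pair_small
        z = np.nanmedian(gt.depth_map_mm)
        d_true = rig_single.baseline_mm * cam_small.focal_px / z
        row = left[64].astype(float)
        row_r = right[64].astype(float)
        lags = np.arange(45, 75)
        score = [np.corrcoef(row[90:140], row_r[90 - k:140 - k])[0, 1]
                 for k in lags]
        best = lags[int(np.argmax(score))]
        assert abs(best - d_true) <= 0.5 + 0.5  # integer lag vs subpixel truth
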