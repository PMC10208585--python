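"""Back-projection, stage-frame registration, merging, cylinder fitting and
contour/vessel co-registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rotastereo as rs
from rotastereo.fusion import (FitError, PointCloud, coregister_modalities,
                               depth_to_cloud, fit_cylinder, merge_clouds,
                               to_stage_frame)
from rotastereo.geometry import DepthMap, rotation_y


def _cylinder_samples(radius=20.0, height=50.0, n=4000, noise=0.0, seed=0,
                      phi_span=(0, 2 * np.pi)):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(*phi_span, n)
    y = rng.uniform(-height / 2, height / 2, n)
    r = radius + noise * rng.standard_normal(n)
    return np.column_stack([r * np.sin(phi), y, r * np.cos(phi)])


class TestDepthToCloud:
    def test_principal_point_maps_to_optical_axis(self, cam_small):
        z = np.full((cam_small.image_height_px, cam_small.image_width_px),
                    np.nan, np.float32)
        valid = np.zeros_like(z, bool)
        cx, cy = map(int, cam_small.principal_point_px)
        z[cy, cx] = 440.0
        valid[cy, cx] = True
        cloud = depth_to_cloud(DepthMap(z, valid), None, cam_small)
        assert np.allclose(cloud.points_mm[0], [0.0, 0.0, 440.0], atol=1e-9)

    def test_backproject_reproject_roundtrip(self, cam_small):
        rng = np.random.default_rng(1)
        z = rng.uniform(400, 480, (cam_small.image_height_px,
                                   cam_small.image_width_px)).astype(np.float32)
        valid = rng.random(z.shape) < 0.1
        cloud = depth_to_cloud(DepthMap(z, valid), None, cam_small)
        vv, uu = np.nonzero(valid)
        cx, cy = cam_small.principal_point_px
        fp = cam_small.focal_px
        pts = cloud.points_mm
        u_back = cx + fp * pts[:, 0] / pts[:, 2]
        v_back = cy + fp * pts[:, 1] / pts[:, 2]
        assert np.abs(u_back - uu).max() < 1e-6
        assert np.abs(v_back - vv).max() < 1e-6

    def test_empty_depth_gives_empty_cloud(self, cam_small):
        z = np.zeros((4, 4), np.float32)
        cloud = depth_to_cloud(DepthMap(z, np.zeros((4, 4), bool)), None,
                               rs.CameraModel(image_width_px=4,
                                              image_height_px=4,
                                              principal_point_px=(2, 2)))
        assert len(cloud) == 0

    def test_reconstructed_plane_is_planar(self, plane_pair_small, cam_small,
                                           rig_single):
        """Cloud of a matched plane stays within 2x the depth resolution of
        the best-fit plane."""
        spec, left, right, gt = plane_pair_small
        cfg = rs.default_match_config(cam_small, rig_single, spec, "contour")
        disp = rs.match_pair(left, right, cfg)  # fixture is already rectified
        depth = rs.triangulate_depth(disp, cam_small, rig_single)
        cloud = depth_to_cloud(depth, left, cam_small)
        pts = cloud.points_mm - cloud.points_mm.mean(axis=0)
        _, svals, vt = np.linalg.svd(pts, full_matrices=False)
        dist = np.abs(pts @ vt[2])
        z = float(np.nanmedian(gt.depth_map_mm))
        budget = rs.depth_resolution(z, cam_small.focal_length_mm,
                                     rig_single.baseline_mm,
                                     cam_small.pixel_pitch_mm / 2)
        assert len(cloud) > 1500
        assert np.percentile(dist, 99) < 2 * budget


class TestStageFrame:
    def test_station_zero_applies_no_stage_rotation(self, rig):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-10, 10, (50, 3)) + [0, 0, 440]
        cloud = PointCloud(points_mm=pts)
        out = to_stage_frame(cloud, 0.0, rig)
        # axis flip + translation only: differences of points are preserved
        # up to the fixed flip, with no rotation about the vertical axis
        d_in = np.diff(pts, axis=0) @ np.diag([1.0, -1.0, -1.0])
        d_out = np.diff(out.points_mm, axis=0)
        assert np.allclose(d_in, d_out, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0, 360), st.integers(0, 2 ** 31 - 1))
    def test_rigid_transform_preserves_distances(self, station, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, (20, 3))
        rig = rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0)
        out = to_stage_frame(PointCloud(points_mm=pts), station, rig)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out.points_mm[:, None] - out.points_mm[None, :],
                               axis=-1)
        assert np.abs(d_in - d_out).max() < 1e-9

    def test_full_circle_closure(self):
        r = np.eye(3)
        for _ in range(8):
            r = rotation_y(45.0) @ r
        assert np.allclose(r, np.eye(3), atol=1e-12)

    def test_same_point_from_two_stations_coincides(self, cam_small, rig,
                                                    cylinder_spec):
        """Ground-truth depth maps from stations 0 and 90 land on the same
        stage-frame cylinder surface where their views overlap (rotating the
        stage by +s brings object azimuth -s in front of the camera)."""
        from scipy.spatial import cKDTree
        clouds = {}
        for station in (0.0, 90.0):
            gt = rs.ground_truth_view(cylinder_spec, cam_small, rig, station,
                                      "left", rectified=True)
            depth = DepthMap(gt.depth_map_mm, np.isfinite(gt.depth_map_mm))
            cloud = depth_to_cloud(depth, None, cam_small)
            clouds[station] = to_stage_frame(cloud, station, rig).points_mm
        # all points lie on the radius-20 cylinder
        for pts in clouds.values():
            radial = np.linalg.norm(pts[:, [0, 2]], axis=1)
            assert np.abs(radial - 20.0).max() < 0.05
        # the views overlap around object azimuth -45 deg
        def in_overlap(pts):
            az = np.rad2deg(np.arctan2(pts[:, 0], pts[:, 2]))
            return pts[(az > -55) & (az < -35) & (np.abs(pts[:, 1]) < 20)]
        a, b = in_overlap(clouds[0.0]), in_overlap(clouds[90.0])
        assert len(a) > 50 and len(b) > 50
        d, _ = cKDTree(a).query(b)
        # discrete sampling: one pixel column spans ~1 mm of arc here, so
        # agreement well below that pitch means the surfaces coincide
        assert np.median(d) < 0.5


class TestMerge:
    def test_self_merge_is_idempotent(self):
        pts = _cylinder_samples(n=3000, seed=3)
        cloud = PointCloud(points_mm=pts)
        merged = merge_clouds([cloud, cloud], voxel_mm=0.1)
        assert abs(len(merged) - len(cloud)) <= 0.05 * len(cloud)

    def test_zero_voxel_concatenates(self):
        a = PointCloud(points_mm=np.zeros((5, 3)))
        b = PointCloud(points_mm=np.ones((7, 3)))
        assert len(merge_clouds([a, b], voxel_mm=0.0)) == 12

    def test_empty_input(self):
        assert len(merge_clouds([], voxel_mm=0.1)) == 0

    def test_eight_station_merge_covers_circumference(self, cam_full, rig,
                                                      cylinder_spec):
        """Fusing ground-truth depth from all 8 stations covers >=350 deg of
        the cylinder's azimuth (full-resolution camera: one pixel column
        subtends ~0.7 deg of azimuth at the facing surface)."""
        clouds = []
        for station in rig.station_angles_deg:
            gt = rs.ground_truth_view(cylinder_spec, cam_full, rig, station,
                                      "left", rectified=True)
            depth = DepthMap(gt.depth_map_mm, np.isfinite(gt.depth_map_mm))
            clouds.append(to_stage_frame(depth_to_cloud(depth, None,
                                                        cam_full),
                                         station, rig))
        merged = merge_clouds(clouds, voxel_mm=0.2)
        az = np.rad2deg(np.arctan2(merged.points_mm[:, 0],
                                   merged.points_mm[:, 2]))
        occupied = np.unique(np.floor(az).astype(int))
        assert len(occupied) >= 350


class TestCylinderFit:
    def test_exact_samples_recover_radius(self):
        cloud = PointCloud(points_mm=_cylinder_samples())
        fit = fit_cylinder(cloud)
        assert fit.radius_mm == pytest.approx(20.0, abs=0.01)
        assert fit.rms_mm < 1e-6
        assert fit.height_mm == pytest.approx(50.0, abs=0.5)

    def test_noisy_samples_within_tolerance(self):
        for seed in range(5):
            cloud = PointCloud(points_mm=_cylinder_samples(noise=0.1,
                                                           seed=seed))
            fit = fit_cylinder(cloud)
            assert fit.radius_mm == pytest.approx(20.0, abs=0.1)

    def test_partial_arc_still_fits(self):
        pts = _cylinder_samples(phi_span=(-np.pi / 3, np.pi / 3), n=2000)
        fit = fit_cylinder(PointCloud(points_mm=pts))
        assert fit.radius_mm == pytest.approx(20.0, abs=0.05)

    def test_degenerate_cloud_rejected(self):
        rng = np.random.default_rng(5)
        flat = rng.uniform(-10, 10, (200, 3))
        flat[:, 2] = 4.0  # coplanar
        with pytest.raises(FitError):
            fit_cylinder(PointCloud(points_mm=flat))
        with pytest.raises(FitError):
            fit_cylinder(PointCloud(points_mm=flat[:10]))


class TestCoregistration:
    def test_surface_vessels_have_zero_depth(self):
        surface = PointCloud(points_mm=_cylinder_samples(n=8000, seed=6))
        on_surf = PointCloud(points_mm=_cylinder_samples(n=300, seed=7))
        fused = coregister_modalities(surface, on_surf)
        assert np.abs(fused.vessels.relative_depth_mm).max() < 0.3

    def test_subsurface_vessels_recovered_at_minus_three(self):
        surface = PointCloud(points_mm=_cylinder_samples(n=8000, seed=8))
        buried = _cylinder_samples(radius=17.0, n=300, seed=9,
                                   phi_span=(0.2, 1.0))
        fused = coregister_modalities(surface,
                                      PointCloud(points_mm=buried))
        rel = fused.vessels.relative_depth_mm
        assert np.median(rel) == pytest.approx(-3.0, abs=0.5)
        assert (rel < 0).mean() > 0.95

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            coregister_modalities(PointCloud(points_mm=np.empty((0, 3))),
                                  PointCloud(points_mm=np.ones((3, 3))))
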