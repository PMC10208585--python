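"""Shared fixtures.

Tests run on a reduced camera (161x129 px, 0.08 mm pitch — same field of
view as the full 640x512 / 0.02 mm sensor at a quarter the resolution)
wherever full resolution is not the point, to keep the suite fast.
"""

import numpy as np
import pytest

import rotastereo as rs


@pytest.fixture(scope="session")
def cam_full() -> rs.CameraModel:
    return rs.CameraModel()


@pytest.fixture(scope="session")
def cam_small() -> rs.CameraModel:
    return rs.CameraModel(focal_length_mm=35.0, pixel_pitch_mm=0.08,
                          image_width_px=161, image_height_px=129)


@pytest.fixture(scope="session")
def rig() -> rs.RotationalRig:
    return rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0)


@pytest.fixture(scope="session")
def rig_single() -> rs.RotationalRig:
    return rs.RotationalRig(stage_distance_mm=440.0, baseline_mm=60.0,
                            station_angles_deg=(0.0,))


@pytest.fixture(scope="session")
def cylinder_spec() -> rs.PhantomSpec:
    return rs.cylinder_phantom(0)


@pytest.fixture(scope="session")
def plane_pair_small(cam_small, rig_single):
    """Noiseless rectified-pose renders of a random-textured plane."""
    spec = rs.plane_phantom(0)
    left, gt = rs.render_view(spec, cam_small, rig_single, 0.0, "left", 1,
                              "contour", noise=False, rectified_pose=True)
    right, _ = rs.render_view(spec, cam_small, rig_single, 0.0, "right", 1,
                              "contour", noise=False, rectified_pose=True)
    return spec, left, right, gt


@pytest.fixture(scope="session")
def cylinder_fluor_small(cam_small, rig_single, cylinder_spec):
    """Fluorescence view of the cylinder phantom with centreline truth."""
    img, gt = rs.render_view(cylinder_spec, cam_small, rig_single, 0.0,
                             "left", 2, "fluorescence")
    return img, gt


def analytic_cylinder_depth(cam, rig, spec, station_deg, eye, u, v):
    """Independent closed-form camera depth of the cylinder surface for a
    rectified eye view: intersect the pixel ray from the eye centre at
    (-/+ b/2, 0, D cos t) looking along -z with x^2 + z^2 = r^2."""
    sgn = 1.0 if eye == "left" else -1.0
    cx, cy = cam.principal_point_px
    fp = cam.focal_px
    ox = -sgn * rig.baseline_mm / 2.0
    oz = rig.mid_view_distance_mm
    # object-frame ray for station 0: direction ((u-cx)/fp, ..., -1) * t
    dx = (np.asarray(u, float) - cx) / fp
    r2 = spec.cylinder_radius_mm ** 2
    # (ox + t*dx)^2 + (oz - t)^2 = r^2  with camera depth z_c = t
    a = dx ** 2 + 1.0
    b = 2.0 * (ox * dx - oz)
    c = ox ** 2 + oz ** 2 - r2
    disc = b ** 2 - 4 * a * c
    t = np.where(disc >= 0, (-b - np.sqrt(np.maximum(disc, 0))) / (2 * a), np.nan)
    return t
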