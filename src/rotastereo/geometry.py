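"""Rotational-stereo camera geometry.

A single camera images a scene sitting on a rotary stage.  Rotating the
stage by +/- theta about its vertical axis is equivalent to imaging with two
virtual cameras placed on a chord of the rotation circle; the chord length

    b = 2 * D * sin(theta)

is the stereo baseline, where ``D`` is the distance from the camera to the
stage axis.  After de-rotating each view by -/+ theta onto the virtual
mid-view, the pair is a standard rectified stereo rig: corresponding points
share image rows and depth follows the triangulation relation ``Z = b*f/d``
with ``d`` the disparity expressed in millimetres on the sensor.

Coordinate conventions
----------------------
* Images are row-major, origin top-left; ``u`` is the column, ``v`` the row.
* Camera frame: x right, y down, z along the optical axis into the scene.
* Stage (object) frame: right-handed, +y is the vertical rotation axis
  (up), +z points from the stage toward the camera.  The camera centre sits
  at stage coordinates ``(0, 0, D)``.

The mapping between frames is the fixed flip ``M = diag(1, -1, -1)``
(camera y-down vs stage y-up, opposing z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "CameraModel",
    "RotationalRig",
    "DisparityMap",
    "DepthMap",
    "baseline_from_rotation",
    "half_angle_from_baseline",
    "depth_resolution",
    "triangulate_depth",
    "rectify_pair",
    "rectification_homography",
    "camera_pose",
    "project_points",
    "rotation_y",
    "AXIS_FLIP",
]

#: Fixed camera<->stage axis alignment: image y-down vs stage y-up, opposing z.
AXIS_FLIP = np.diag([1.0, -1.0, -1.0])


def rotation_y(angle_deg: float) -> np.ndarray:
    """Right-handed rotation about the +y (vertical stage) axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def baseline_from_rotation(stage_distance_mm: float, half_angle_deg: float) -> float:
    """Stereo baseline of a rotational rig: chord between the virtual eyes.

    b = 2 * D * sin(theta); theta must lie strictly in (0, 90) degrees.
    """
    if stage_distance_mm <= 0:
        raise ValueError(f"stage distance must be positive, got {stage_distance_mm}")
    if not 0 < half_angle_deg < 90:
        raise ValueError(f"half angle must lie in (0, 90) deg, got {half_angle_deg}")
    return 2.0 * stage_distance_mm * np.sin(np.deg2rad(half_angle_deg))


def half_angle_from_baseline(stage_distance_mm: float, baseline_mm: float) -> float:
    """Inverse of :func:`baseline_from_rotation` (degrees)."""
    if stage_distance_mm <= 0 or baseline_mm <= 0:
        raise ValueError("stage distance and baseline must be positive")
    if baseline_mm >= 2 * stage_distance_mm:
        raise ValueError("baseline must be shorter than the rotation-circle diameter")
    return float(np.rad2deg(np.arcsin(baseline_mm / (2.0 * stage_distance_mm))))


def depth_resolution(z_mm: float, focal_mm: float, baseline_mm: float,
                     matching_error_mm: float) -> float:
    """Smallest distinguishable depth step: Dr = Z^2 / (f*b) * delta_p.

    ``matching_error_mm`` is the disparity matching error expressed in mm on
    the sensor (pixel error times pixel pitch); zero error gives zero Dr.
    """
    if z_mm <= 0 or focal_mm <= 0 or baseline_mm <= 0:
        raise ValueError("Z, f and b must all be positive")
    if matching_error_mm < 0:
        raise ValueError("matching error cannot be negative")
    return z_mm ** 2 / (focal_mm * baseline_mm) * matching_error_mm


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera in physical units.

    Attributes
    ----------
    focal_length_mm : focal length f.
    pixel_pitch_mm : sensor pixel pitch; converts pixel disparities to mm.
    image_width_px, image_height_px : sensor size in pixels.
    principal_point_px : (col, row) of the optical axis; defaults to the
        image centre.
    """

    focal_length_mm: float = 35.0
    pixel_pitch_mm: float = 0.02
    image_width_px: int = 640
    image_height_px: int = 512
    principal_point_px: tuple[float, float] | None = None

    def __post_init__(self):
        if self.focal_length_mm <= 0:
            raise ValueError("focal length must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image size must be positive")
        if self.principal_point_px is None:
            object.__setattr__(
                self, "principal_point_px",
                ((self.image_width_px - 1) / 2.0, (self.image_height_px - 1) / 2.0))
        cx, cy = self.principal_point_px
        if not (0 <= cx < self.image_width_px and 0 <= cy < self.image_height_px):
            raise ValueError("principal point must lie inside the image")

    @property
    def focal_px(self) -> float:
        """Focal length in pixel units, f / pitch."""
        return self.focal_length_mm / self.pixel_pitch_mm

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        cx, cy = self.principal_point_px
        fp = self.focal_px
        return np.array([[fp, 0.0, cx], [0.0, fp, cy], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class RotationalRig:
    """Rotary-stage geometry and the derived stereo baseline.

    Either ``baseline_mm`` or ``half_angle_deg`` may be given; the missing
    one is derived through b = 2*D*sin(theta).  If both are supplied the
    explicit baseline wins and theta is kept as given (the two views are
    then treated as a verged pair with that baseline).
    """

    stage_distance_mm: float = 440.0
    half_angle_deg: float | None = None
    baseline_mm: float | None = None
    station_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0,
                                             180.0, 225.0, 270.0, 315.0)

    def __post_init__(self):
        if self.stage_distance_mm <= 0:
            raise ValueError("stage distance must be positive")
        if self.baseline_mm is None and self.half_angle_deg is None:
            raise ValueError("supply baseline_mm and/or half_angle_deg")
        if self.baseline_mm is None:
            object.__setattr__(
                self, "baseline_mm",
                baseline_from_rotation(self.stage_distance_mm, self.half_angle_deg))
        if self.half_angle_deg is None:
            object.__setattr__(
                self, "half_angle_deg",
                half_angle_from_baseline(self.stage_distance_mm, self.baseline_mm))
        if not 0 < self.baseline_mm < 2 * self.stage_distance_mm:
            raise ValueError("baseline must lie in (0, 2*D)")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half angle must lie in (0, 90) deg")
        ang = np.mod(np.asarray(self.station_angles_deg, dtype=float), 360.0)
        if len(ang) == 0:
            raise ValueError("at least one station angle required")
        if len(np.unique(np.round(ang, 9))) != len(ang):
            raise ValueError("station angles must be distinct modulo 360")
        object.__setattr__(self, "station_angles_deg", tuple(np.asarray(
            self.station_angles_deg, dtype=float)))

    @property
    def mid_view_distance_mm(self) -> float:
        """Distance from either rectified eye to the stage-axis plane,
        D*cos(theta): the depth at which disparity equals b*f/(D cos theta)."""
        return self.stage_distance_mm * np.cos(np.deg2rad(self.half_angle_deg))


@dataclass
class DisparityMap:
    """Per-pixel disparity in pixels (d = x_left - x_right) with validity."""

    values_px: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.values_px = np.asarray(self.values_px, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values_px.shape != self.valid_mask.shape:
            raise ValueError("disparity and mask shapes differ")


@dataclass
class DepthMap:
    """Metric depth (camera z, mm) with optional depth below a reference
    surface (negative below, matching the 0 to -5 mm imaging-depth
    convention)."""

    z_mm: np.ndarray
    valid_mask: np.ndarray
    relative_depth_mm: np.ndarray | None = None

    def __post_init__(self):
        self.z_mm = np.asarray(self.z_mm, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.z_mm.shape != self.valid_mask.shape:
            raise ValueError("depth and mask shapes differ")


def triangulate_depth(disparity: DisparityMap, cam: CameraModel,
                      rig: RotationalRig) -> DepthMap:
    """Convert a disparity map to metric depth via Z = b*f/d.

    Disparities are in pixels and converted to sensor mm with the camera's
    pixel pitch.  Pixels with non-positive disparity are marked invalid
    rather than producing negative or infinite depth.
    """
    d_px = disparity.values_px
    valid = disparity.valid_mask & (d_px > 0) & np.isfinite(d_px)
    if not valid.any():
        warnings.warn("all disparities invalid; returning an empty depth map",
                      stacklevel=2)
    z = np.full(d_px.shape, np.nan, dtype=np.float32)
    d_mm = d_px[valid] * cam.pixel_pitch_mm
    z[valid] = rig.baseline_mm * cam.focal_length_mm / d_mm
    return DepthMap(z_mm=z, valid_mask=valid)


# ---------------------------------------------------------------------------
# poses and projection

def camera_pose(rig: RotationalRig, station_deg: float, eye: str,
                rectified: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """World-to-camera rotation and camera centre (object frame).

    ``eye='left'`` corresponds to the stage rotated by +theta relative to
    the station heading (virtual camera displaced to -x), ``'right'`` to
    -theta.  With ``rectified=True`` the pose is the de-rotated virtual
    camera of the parallel rig: both eyes share the station's mid-view
    orientation and sit at ``(-/+ b/2, 0, D cos(theta))`` in the
    station-rotated frame.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    sgn = 1.0 if eye == "left" else -1.0
    theta = rig.half_angle_deg
    if rectified:
        r_wc = AXIS_FLIP @ rotation_y(station_deg)
        c_station = np.array([-sgn * rig.baseline_mm / 2.0, 0.0,
                              rig.mid_view_distance_mm])
        centre = rotation_y(-station_deg) @ c_station
    else:
        alpha = station_deg + sgn * theta
        r_wc = AXIS_FLIP @ rotation_y(alpha)
        centre = rotation_y(-alpha) @ np.array([0.0, 0.0, rig.stage_distance_mm])
    return r_wc, centre


def project_points(points_mm: np.ndarray, cam: CameraModel, r_wc: np.ndarray,
                   centre_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pinhole projection of object-frame points.

    Returns (u, v, z_cam): pixel coordinates and camera depth in mm.
    """
    p = np.atleast_2d(points_mm) - centre_mm
    pc = p @ r_wc.T
    z = pc[:, 2]
    fp = cam.focal_px
    cx, cy = cam.principal_point_px
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cx + fp * pc[:, 0] / z
        v = cy + fp * pc[:, 1] / z
    return u, v, z


# ---------------------------------------------------------------------------
# rectification

def rectification_homography(cam: CameraModel, rig: RotationalRig,
                             eye: str) -> np.ndarray:
    """Homography mapping a raw eye view onto the virtual mid-view.

    Rotating the stage by +/- theta is undone by rotating the camera about
    its own centre by the same angle about the (vertical) stage axis, which
    acts on the image as K * R_y(+/- theta) * K^-1.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    sgn = 1.0 if eye == "left" else -1.0
    k = cam.intrinsic_matrix
    r = rotation_y(sgn * rig.half_angle_deg)
    h = k @ r @ np.linalg.inv(k)
    return h / h[2, 2]


def _warp_homography(image: np.ndarray, h: np.ndarray) -> np.ndarray:
    tf = ProjectiveTransform(matrix=np.linalg.inv(h))
    return warp(image.astype(np.float32), tf, order=1, mode="constant",
                cval=0.0, preserve_range=True).astype(np.float32)


def rectify_pair(left: np.ndarray, right: np.ndarray, rig: RotationalRig,
                 cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Warp a raw rotational-stereo pair so epipolar lines are horizontal.

    Each view is de-rotated by -/+ theta about the stage axis onto the
    virtual mid-view; for theta -> 0 this is the identity.  Returns float32
    images; pixels warped in from outside the source are zero.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    if left.shape != right.shape:
        raise ValueError(f"image sizes differ: {left.shape} vs {right.shape}")
    if left.shape != (cam.image_height_px, cam.image_width_px):
        raise ValueError("images do not match the camera model size")
    hl = rectification_homography(cam, rig, "left")
    hr = rectification_homography(cam, rig, "right")
    return _warp_homography(left, hl), _warp_homography(right, hr)
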