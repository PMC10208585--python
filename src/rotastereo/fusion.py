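"""Point-cloud fusion: back-projection, stage-frame registration, merging,
cylinder fitting and contour/vessel co-registration.

Each rectified station pair yields a depth map in the rectified-left camera
frame.  Back-projected clouds are moved into the common stage frame using
the mechanically known station angle (the rotary stage provides the
registration; no ICP is needed for the nominal geometry), concatenated and
voxel-downsampled into a single 360-degree model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import (AXIS_FLIP, CameraModel, DepthMap, RotationalRig,
                       rotation_y)

__all__ = [
    "PointCloud",
    "FusedModel",
    "depth_to_cloud",
    "to_stage_frame",
    "merge_clouds",
    "fit_cylinder",
    "CylinderFit",
    "FitError",
    "coregister_modalities",
]


class FitError(RuntimeError):
    """Raised when a geometric fit is degenerate."""


@dataclass
class PointCloud:
    """3D points in mm with per-point intensity, provenance and optional
    depth below the reference surface (negative below)."""

    points_mm: np.ndarray
    intensity: np.ndarray | None = None
    station_deg: np.ndarray | None = None
    relative_depth_mm: np.ndarray | None = None

    def __post_init__(self):
        self.points_mm = np.asarray(self.points_mm, dtype=np.float64).reshape(-1, 3)
        n = len(self.points_mm)
        if not np.isfinite(self.points_mm).all():
            raise ValueError("point coordinates must be finite")
        for name in ("intensity", "station_deg", "relative_depth_mm"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=np.float64).reshape(-1)
                if len(val) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, val)

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class FusedModel:
    """A contour cloud plus a vessel cloud carrying depth below the skin."""

    contour: PointCloud
    vessels: PointCloud


def depth_to_cloud(depth: DepthMap, texture: np.ndarray | None,
                   cam: CameraModel, station_deg: float | None = None
                   ) -> PointCloud:
    """Pinhole back-projection of valid depth pixels into the camera frame.

    x = (u - cx) Z pitch / f, y = (v - cy) Z pitch / f, z = Z; intensity is
    sampled from ``texture`` at the source pixel.
    """
    valid = depth.valid_mask & np.isfinite(depth.z_mm)
    if texture is not None and np.asarray(texture).shape != depth.z_mm.shape:
        raise ValueError("depth and texture sizes differ")
    vv, uu = np.nonzero(valid)
    z = depth.z_mm[vv, uu].astype(np.float64)
    cx, cy = cam.principal_point_px
    scale = z / cam.focal_px
    pts = np.column_stack([(uu - cx) * scale, (vv - cy) * scale, z])
    inten = np.asarray(texture)[vv, uu].astype(np.float64) \
        if texture is not None else None
    rel = None
    if depth.relative_depth_mm is not None:
        rel = depth.relative_depth_mm[vv, uu].astype(np.float64)
    stat = np.full(len(pts), station_deg, dtype=np.float64) \
        if station_deg is not None else None
    return PointCloud(points_mm=pts, intensity=inten, station_deg=stat,
                      relative_depth_mm=rel)


def to_stage_frame(cloud: PointCloud, station_deg: float, rig: RotationalRig,
                   eye: str = "left") -> PointCloud:
    """Rigid transform from the rectified eye camera frame to the stage frame.

    The camera axes are aligned with the stage axes (image y-down -> stage
    y-up, opposing z), the cloud is translated so the stage axis is the
    origin (the rectified eye sits at (-/+ b/2, 0, D cos theta)), and at
    station 0 no stage-axis rotation is applied; other stations rotate by
    -station_deg about the vertical axis.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    sgn = 1.0 if eye == "left" else -1.0
    centre = np.array([-sgn * rig.baseline_mm / 2.0, 0.0,
                       rig.mid_view_distance_mm])
    pts = cloud.points_mm @ AXIS_FLIP.T + centre
    pts = pts @ rotation_y(-station_deg).T
    return PointCloud(points_mm=pts, intensity=cloud.intensity,
                      station_deg=cloud.station_deg,
                      relative_depth_mm=cloud.relative_depth_mm)


def merge_clouds(clouds: list[PointCloud], voxel_mm: float = 0.1) -> PointCloud:
    """Concatenate stage-frame clouds and voxel-downsample.

    Each occupied voxel is replaced by the centroid of its points with
    averaged intensity/relative depth; the station tag of the first
    contributing point is kept as provenance.  ``voxel_mm <= 0`` degenerates
    to pure concatenation.
    """
    clouds = [c for c in clouds if len(c) > 0]
    if not clouds:
        return PointCloud(points_mm=np.empty((0, 3)))

    def _cat(attr, fill):
        cols = []
        for c in clouds:
            val = getattr(c, attr)
            cols.append(val if val is not None
                        else np.full(len(c), fill, dtype=np.float64))
        return np.concatenate(cols)

    pts = np.concatenate([c.points_mm for c in clouds])
    inten = _cat("intensity", 0.0)
    stat = _cat("station_deg", -1.0)
    rel = _cat("relative_depth_mm", np.nan)
    if voxel_mm <= 0:
        return PointCloud(pts, inten, stat, rel)
    keys = np.floor(pts / voxel_mm).astype(np.int64)
    _, first_idx, inv = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    n_vox = len(first_idx)
    counts = np.bincount(inv, minlength=n_vox).astype(np.float64)

    def _mean(values):
        return np.bincount(inv, weights=values, minlength=n_vox) / counts

    centroids = np.column_stack([_mean(pts[:, k]) for k in range(3)])
    # NaN-aware mean of the relative-depth attribute
    rel_cnt = np.bincount(inv, weights=np.isfinite(rel).astype(float),
                          minlength=n_vox)
    rel_sum = np.bincount(inv, weights=np.where(np.isfinite(rel), rel, 0.0),
                          minlength=n_vox)
    rel_out = np.where(rel_cnt > 0, rel_sum / np.maximum(rel_cnt, 1.0), np.nan)
    return PointCloud(points_mm=centroids, intensity=_mean(inten),
                      station_deg=stat[first_idx], relative_depth_mm=rel_out)


@dataclass
class CylinderFit:
    """Least-squares cylinder: a point on the axis, the unit axis direction,
    radius, extent along the axis and the RMS radial residual (all mm)."""

    axis_point_mm: np.ndarray
    axis_direction: np.ndarray
    radius_mm: float
    height_mm: float
    rms_mm: float


def _axis_direction(tilt_x: float, tilt_z: float) -> np.ndarray:
    """Near-vertical unit axis parameterized by two small tilt angles."""
    d = np.array([np.sin(tilt_x), np.cos(tilt_x) * np.cos(tilt_z),
                  np.cos(tilt_x) * np.sin(tilt_z)])
    return d / np.linalg.norm(d)


def fit_cylinder(cloud: PointCloud, extent_percentile: float = 0.1
                 ) -> CylinderFit:
    """Least-squares cylinder with vertical-axis initialization.

    Parameters are the axis foot point (x0, z0) at y=0, two tilt angles and
    the radius; residuals are point-to-axis distance minus radius with a
    soft-L1 loss for robustness to matching outliers.  Height is the
    (percentile-trimmed) extent of the points along the fitted axis.
    """
    pts = cloud.points_mm
    if len(pts) < 50:
        raise FitError(f"need at least 50 points, got {len(pts)}")
    svals = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if svals[-1] < 1e-9 * max(svals[0], 1.0):
        raise FitError("degenerate (coplanar) point cloud")

    def residuals(params):
        x0, z0, tx, tz, r = params
        d = _axis_direction(tx, tz)
        rel = pts - np.array([x0, 0.0, z0])
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1) - r

    x0 = pts[:, 0].mean()
    z0 = pts[:, 2].mean()
    r0 = np.linalg.norm(pts[:, [0, 2]] - [x0, z0], axis=1).mean()
    res = least_squares(residuals, x0=[x0, z0, 0.0, 0.0, r0],
                        loss="soft_l1", f_scale=1.0)
    if not res.success or res.x[4] <= 0:
        raise FitError(f"cylinder fit failed: {res.message}")
    x0, z0, tx, tz, r = res.x
    d = _axis_direction(tx, tz)
    along = (pts - np.array([x0, 0.0, z0])) @ d
    lo, hi = np.percentile(along, [extent_percentile, 100.0 - extent_percentile])
    final = residuals(res.x)
    return CylinderFit(axis_point_mm=np.array([x0, 0.0, z0]),
                       axis_direction=d, radius_mm=float(r),
                       height_mm=float(hi - lo),
                       rms_mm=float(np.sqrt(np.mean(final ** 2))))


def _surface_normals(pts: np.ndarray, surf: np.ndarray, tree: cKDTree,
                     k: int = 20) -> np.ndarray:
    """PCA normals of the surface cloud at query points ``pts``, oriented
    away from the vertical stage axis (outward for a body on the stage)."""
    k = min(k, len(surf))
    _, idx = tree.query(pts, k=k)
    neigh = surf[np.atleast_2d(idx)]
    centred = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / k
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    radial = pts.copy()
    radial[:, 1] = 0.0
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = np.divide(radial, norms, out=np.zeros_like(radial),
                       where=norms > 1e-9)
    flip = np.einsum("ij,ij->i", normals, radial) < 0
    normals[flip] *= -1.0
    return normals


def coregister_modalities(contour_cloud: PointCloud, vessel_cloud: PointCloud,
                          k_neighbors: int = 20) -> FusedModel:
    """Attach depth-below-surface to vessel points using the contour cloud.

    Both clouds must already share the stage frame (same acquisition
    geometry).  For each vessel point the signed distance to the nearest
    contour point along the local surface normal is stored as
    ``relative_depth_mm`` (negative below the surface).
    """
    if len(contour_cloud) == 0:
        raise ValueError("contour cloud is empty")
    surf = contour_cloud.points_mm
    tree = cKDTree(surf)
    if len(vessel_cloud) == 0:
        return FusedModel(contour=contour_cloud, vessels=vessel_cloud)
    _, nearest = tree.query(vessel_cloud.points_mm, k=1)
    anchors = surf[nearest]
    normals = _surface_normals(anchors, surf, tree, k=k_neighbors)
    rel = np.einsum("ij,ij->i", vessel_cloud.points_mm - anchors, normals)
    vessels = PointCloud(points_mm=vessel_cloud.points_mm,
                         intensity=vessel_cloud.intensity,
                         station_deg=vessel_cloud.station_deg,
                         relative_depth_mm=rel)
    return FusedModel(contour=contour_cloud, vessels=vessels)
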