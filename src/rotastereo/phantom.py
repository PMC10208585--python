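"""Synthetic rotational-stereo scenes with ground truth.

Renders left/right eye views of analytic phantoms through the pinhole
camera of :mod:`rotastereo.geometry`:

* ``cylinder`` — a vertical circular cylinder (default radius 20 mm,
  height 50 mm) carrying a helical vessel pattern on its surface; the
  contour-imaging validation object.
* ``mouse_body`` — a vertical elliptical cylinder standing in for a small
  animal body, with a branching vessel tree buried 0 to -5 mm below the
  surface (the NIR-II imaging-depth envelope).
* ``plane`` — a fronto-parallel textured plane, used as a calibration-style
  fixture in tests.

Two illumination modes share one renderer: ``contour`` emulates broadband
lamp illumination (shaded, textured surface; vessels optionally imprinted
as dark paint), ``fluorescence`` emulates 793 nm excitation with long-pass
NIR-II detection (bright vessels over a faint body glow).  Subsurface
vessels are attenuated as exp(depth/l) and blurred with a Gaussian whose
sigma grows linearly with |depth| — a deliberate, parameterized
simplification of tissue scattering, not a physical light-transport model.
Shot noise is Poisson on the photon scale plus additive Gaussian read
noise; every random choice flows from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import CameraModel, RotationalRig, camera_pose, project_points

__all__ = [
    "VesselSegment",
    "PhantomSpec",
    "GroundTruth",
    "cylinder_phantom",
    "mouse_phantom",
    "plane_phantom",
    "render_view",
    "render_acquisition",
    "ground_truth_view",
]

MIN_DEPTH_MM = -5.0  # imaging-depth envelope: vessels live in [-5, 0] mm


@dataclass(frozen=True)
class VesselSegment:
    """A vessel polyline at constant depth below the phantom surface.

    ``surface_points_mm`` are the anchor points on the surface;
    ``points_mm`` are the same points pushed inward along the local surface
    normal by |depth_mm| (depth <= 0).
    """

    points_mm: np.ndarray
    surface_points_mm: np.ndarray
    normals: np.ndarray
    radius_mm: float
    depth_mm: float

    def __post_init__(self):
        if not MIN_DEPTH_MM <= self.depth_mm <= 0:
            raise ValueError(
                f"vessel depth {self.depth_mm} outside [{MIN_DEPTH_MM}, 0] mm")
        if self.radius_mm <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description plus the optical parameters of the forward model."""

    kind: str = "cylinder"
    cylinder_radius_mm: float = 20.0
    cylinder_height_mm: float = 50.0
    body_semi_axes_mm: tuple[float, float] = (14.0, 9.0)
    body_height_mm: float = 60.0
    plane_half_extent_mm: tuple[float, float] = (40.0, 30.0)
    plane_z_mm: float = 0.0
    vessel_pattern: tuple[VesselSegment, ...] = ()
    surface_texture_seed: int = 0
    texture_kind: str = "random"       # 'random' | 'sinusoid'
    texture_period_mm: float = 2.0     # sinusoid period
    imprint_vessels: bool = False      # paint vessels dark in contour mode
    attenuation_length_mm: float = 2.0
    blur_px_per_mm: float = 0.5
    base_blur_px: float = 0.6
    body_glow: float = 0.03
    photon_scale: float = 20000.0
    read_noise_counts: float = 3.0

    def __post_init__(self):
        if self.kind not in ("cylinder", "mouse_body", "plane"):
            raise ValueError(f"unknown phantom kind '{self.kind}'")
        if self.cylinder_radius_mm <= 0 or self.cylinder_height_mm <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if min(self.body_semi_axes_mm) <= 0 or self.body_height_mm <= 0:
            raise ValueError("body dimensions must be positive")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        """(a_x, a_z, height) of the surface of revolution."""
        if self.kind == "cylinder":
            r = self.cylinder_radius_mm
            return r, r, self.cylinder_height_mm
        return (*self.body_semi_axes_mm, self.body_height_mm)


@dataclass
class GroundTruth:
    """Per-rendered-view truth used for parameter-recovery tests.

    ``depth_map_mm`` is the camera depth of the first surface hit (NaN off
    the object); ``vessel_depth_map_mm`` the camera depth of vessel
    centreline samples at the pixels of ``vessel_centerline_mask``.
    """

    depth_map_mm: np.ndarray
    vessel_centerline_mask: np.ndarray
    vessel_depth_map_mm: np.ndarray
    station_deg: float
    eye: str
    rectified: bool


# ---------------------------------------------------------------------------
# default scenes

def _surface_anchor(spec: PhantomSpec, phi_deg: np.ndarray,
                    y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Surface points and outward normals at azimuth phi (deg, 0 faces the
    camera at station 0) and height y."""
    ax, az, _ = spec.semi_axes
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    y = np.asarray(y, dtype=float)
    pts = np.column_stack([ax * np.sin(phi), y, az * np.cos(phi)])
    n = np.column_stack([np.sin(phi) / ax, np.zeros_like(phi), np.cos(phi) / az])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return pts, n


def _segment_from_params(spec: PhantomSpec, phi_deg: np.ndarray, y: np.ndarray,
                         radius_mm: float, depth_mm: float) -> VesselSegment:
    surf, n = _surface_anchor(spec, phi_deg, y)
    return VesselSegment(points_mm=surf + depth_mm * n, surface_points_mm=surf,
                         normals=n, radius_mm=radius_mm, depth_mm=depth_mm)


def cylinder_phantom(seed: int = 0, n_helices: int = 3,
                     turns: float = 0.75) -> PhantomSpec:
    """The contour-validation cylinder: radius 20 mm, height 50 mm, with
    helical surface vessel stripes (radius 0.4 mm, depth 0)."""
    spec = PhantomSpec(kind="cylinder", surface_texture_seed=seed,
                       imprint_vessels=True)
    half = spec.cylinder_height_mm / 2.0 - 2.0
    y = np.linspace(-half, half, 160)
    segs = []
    for k in range(n_helices):
        phi = 360.0 * k / n_helices + 360.0 * turns * (y + half) / (2 * half)
        segs.append(_segment_from_params(spec, phi, y, radius_mm=0.4,
                                         depth_mm=0.0))
    return replace(spec, vessel_pattern=tuple(segs))


def mouse_phantom(seed: int = 0) -> PhantomSpec:
    """Mouse-like body (elliptical cylinder) with a branching vessel tree
    whose segment depths step from 0 down to -5 mm below the surface."""
    spec = PhantomSpec(kind="mouse_body", surface_texture_seed=seed)
    half = 27.0
    n_seg = 11
    edges = np.linspace(half, -half, n_seg + 1)
    depths = np.linspace(0.0, MIN_DEPTH_MM, n_seg)
    segs = []
    for j in range(n_seg):
        y = np.linspace(edges[j], edges[j + 1], 40)
        phi = 10.0 * np.sin(2 * np.pi * y / 40.0)
        segs.append(_segment_from_params(spec, phi, y, radius_mm=0.4,
                                         depth_mm=float(depths[j])))
    # side branches inherit the local trunk depth
    rng = np.random.default_rng(seed)
    for i, y0 in enumerate((20.0, 12.0, 4.0, -4.0, -12.0, -20.0)):
        j = int(np.clip(np.searchsorted(-edges[1:], -y0), 0, n_seg - 1))
        side = 1.0 if i % 2 == 0 else -1.0
        t = np.linspace(0.0, 1.0, 30)
        phi0 = 10.0 * np.sin(2 * np.pi * y0 / 40.0)
        phi = phi0 + side * (35.0 + 8.0 * rng.standard_normal()) * t
        y = y0 - 8.0 * t
        segs.append(_segment_from_params(spec, phi, y, radius_mm=0.3,
                                         depth_mm=float(depths[j])))
    return replace(spec, vessel_pattern=tuple(segs))


def plane_phantom(seed: int = 0, z_mm: float = 0.0,
                  texture_kind: str = "random",
                  texture_period_mm: float = 2.0) -> PhantomSpec:
    """Fronto-parallel textured plane at object-frame z = z_mm."""
    return PhantomSpec(kind="plane", plane_z_mm=z_mm,
                       surface_texture_seed=seed, texture_kind=texture_kind,
                       texture_period_mm=texture_period_mm)


# ---------------------------------------------------------------------------
# surface raycasting

def _pixel_rays(cam: CameraModel, r_wc: np.ndarray,
                centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Object-frame ray directions scaled so the camera-z component is 1:
    the ray parameter t is then directly the camera depth in mm."""
    u = np.arange(cam.image_width_px)
    v = np.arange(cam.image_height_px)
    uu, vv = np.meshgrid(u, v)
    cx, cy = cam.principal_point_px
    fp = cam.focal_px
    dirs_c = np.stack([(uu - cx) / fp, (vv - cy) / fp, np.ones_like(uu, float)],
                      axis=-1)
    dirs_w = dirs_c @ r_wc  # == (R_wc.T @ d) per pixel
    return dirs_w, centre


def _raycast(spec: PhantomSpec, cam: CameraModel, r_wc: np.ndarray,
             centre: np.ndarray) -> dict[str, np.ndarray]:
    """First intersection of every pixel ray with the phantom surface.

    Returns camera depth ``z`` (NaN = miss), object-frame hit points,
    outward normals and the texture parameterization (s_along, s_around).
    """
    dirs, o = _pixel_rays(cam, r_wc, centre)
    h, w = dirs.shape[:2]
    z = np.full((h, w), np.nan)
    pts = np.full((h, w, 3), np.nan)
    nrm = np.full((h, w, 3), np.nan)
    if spec.kind == "plane":
        dz = dirs[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (spec.plane_z_mm - o[2]) / dz
        p = o + t[..., None] * dirs
        hw, hh = spec.plane_half_extent_mm
        hit = (t > 0) & (np.abs(p[..., 0]) <= hw) & (np.abs(p[..., 1]) <= hh)
        z[hit] = t[hit]
        pts[hit] = p[hit]
        nrm[hit] = (0.0, 0.0, 1.0)
        s_along, s_around = p[..., 1], p[..., 0]
    else:
        a_x, a_z, height = spec.semi_axes
        dx, dy, dz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
        qa = (dx / a_x) ** 2 + (dz / a_z) ** 2
        qb = 2.0 * (o[0] * dx / a_x ** 2 + o[2] * dz / a_z ** 2)
        qc = (o[0] / a_x) ** 2 + (o[2] / a_z) ** 2 - 1.0
        disc = qb ** 2 - 4.0 * qa * qc
        ok = (disc >= 0) & (qa > 0)
        t = np.full((h, w), np.nan)
        t[ok] = (-qb[ok] - np.sqrt(disc[ok])) / (2.0 * qa[ok])
        p = o + t[..., None] * dirs
        hit = ok & (t > 0) & (np.abs(p[..., 1]) <= height / 2.0)
        z[hit] = t[hit]
        pts[hit] = p[hit]
        n = np.stack([p[..., 0] / a_x ** 2, np.zeros((h, w)),
                      p[..., 2] / a_z ** 2], axis=-1)
        with np.errstate(invalid="ignore"):
            n /= np.linalg.norm(n, axis=-1, keepdims=True)
        nrm[hit] = n[hit]
        # arclength-like parameterization: mean-radius azimuth arc, height
        phi = np.arctan2(p[..., 0] / a_x, p[..., 2] / a_z)
        s_around = 0.5 * (a_x + a_z) * phi
        s_along = p[..., 1]
    return {"z": z, "points": pts, "normals": nrm, "hit": hit,
            "s_along": s_along, "s_around": s_around}


# ---------------------------------------------------------------------------
# texture

_TEXTURE_SPACING_MM = 0.25


def _texture_sampler(spec: PhantomSpec):
    """Seeded multi-octave random albedo field on the surface chart.

    Returns a callable (s_along, s_around) -> albedo in [0.3, 1].  The
    chart is periodic around the surface of revolution so the texture is
    seamless under stage rotation.
    """
    if spec.texture_kind == "sinusoid":
        period = spec.texture_period_mm

        def sample_sin(s_along, s_around):
            return 0.65 + 0.35 * np.sin(2 * np.pi * s_around / period)

        return sample_sin

    if spec.kind == "plane":
        hw, hh = spec.plane_half_extent_mm
        extent_along, extent_around = 2.0 * hh, 2.0 * hw
        periodic = False
        origin_along, origin_around = -hh, -hw
    else:
        a_x, a_z, height = spec.semi_axes
        extent_along = height
        extent_around = 0.5 * (a_x + a_z) * 2.0 * np.pi
        periodic = True
        origin_along, origin_around = -height / 2.0, -extent_around / 2.0
    n_along = max(int(np.ceil(extent_along / _TEXTURE_SPACING_MM)), 8)
    n_around = max(int(np.ceil(extent_around / _TEXTURE_SPACING_MM)), 8)
    rng = np.random.default_rng(spec.surface_texture_seed)
    base = rng.standard_normal((n_along, n_around))
    mode = ("nearest", "wrap") if periodic else "nearest"
    coarse = ndimage.gaussian_filter(base, sigma=6.0, mode=mode)
    fine = ndimage.gaussian_filter(base, sigma=1.2, mode=mode)
    fld = 0.55 * coarse / max(coarse.std(), 1e-9) + \
        0.45 * fine / max(fine.std(), 1e-9)
    fld = 0.65 + 0.22 * fld
    fld = np.clip(fld, 0.3, 1.0)

    def sample(s_along, s_around):
        i = (np.asarray(s_along) - origin_along) / _TEXTURE_SPACING_MM
        j = (np.asarray(s_around) - origin_around) / _TEXTURE_SPACING_MM
        jmode = "grid-wrap" if periodic else "nearest"
        return ndimage.map_coordinates(fld, [i, j], order=1, mode=jmode)

    return sample


# ---------------------------------------------------------------------------
# vessel splatting

def _vessel_samples(spec: PhantomSpec, step_mm: float = 0.15):
    """Dense centreline samples: positions, surface anchors, normals,
    arclength, radius, depth, per-segment modulation phase."""
    if not spec.vessel_pattern:
        return None
    rng = np.random.default_rng(spec.surface_texture_seed + 1)
    pos, anchors, normals, arclen, radius, depth, phase = ([] for _ in range(7))
    for seg in spec.vessel_pattern:
        p = np.asarray(seg.points_mm, dtype=float)
        d = np.diff(p, axis=0)
        seglen = np.linalg.norm(d, axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s[-1]
        n_samp = max(int(np.ceil(total / step_mm)), 2)
        si = np.linspace(0.0, total, n_samp)

        def interp(arr):
            return np.column_stack([np.interp(si, s, arr[:, k])
                                    for k in range(arr.shape[1])])

        pos.append(interp(p))
        anchors.append(interp(np.asarray(seg.surface_points_mm, dtype=float)))
        nn = interp(np.asarray(seg.normals, dtype=float))
        normals.append(nn / np.linalg.norm(nn, axis=1, keepdims=True))
        arclen.append(si)
        radius.append(np.full(n_samp, seg.radius_mm))
        depth.append(np.full(n_samp, seg.depth_mm))
        phase.append(np.full(n_samp, rng.uniform(0, 2 * np.pi)))
    return {k: np.concatenate(v) for k, v in zip(
        ("pos", "anchor", "normal", "arclen", "radius", "depth", "phase"),
        (pos, anchors, normals, arclen, radius, depth, phase))}


def _splat(shape: tuple[int, int], u: np.ndarray, v: np.ndarray,
           amp: np.ndarray, sigma: np.ndarray, step_mm: float,
           mm_per_px: np.ndarray) -> np.ndarray:
    """Accumulate Gaussian blobs; an isolated straight tube peaks at ~amp.

    Each sample deposits amp * (step_px / (sigma sqrt(2 pi))) *
    exp(-rho^2 / 2 sigma^2); summed along a line this integrates to the
    transverse Gaussian profile with peak amp.
    """
    h, w = shape
    img = np.zeros(h * w)
    if len(u) == 0:
        return img.reshape(h, w)
    k = int(np.ceil(3.0 * sigma.max()))
    offs = np.arange(-k, k + 1)
    cu = np.rint(u).astype(np.int64)
    cv = np.rint(v).astype(np.int64)
    uu = cu[:, None, None] + offs[None, :, None]
    vv = cv[:, None, None] + offs[None, None, :]
    rho2 = (uu - u[:, None, None]) ** 2 + (vv - v[:, None, None]) ** 2
    step_px = step_mm / mm_per_px
    norm = amp * step_px / (sigma * np.sqrt(2 * np.pi))
    contrib = norm[:, None, None] * np.exp(-rho2 / (2.0 * sigma[:, None, None] ** 2))
    inb = (uu >= 0) & (uu < w) & (vv >= 0) & (vv < h)
    flat = (vv * w + uu)[inb]
    img += np.bincount(flat, weights=contrib[inb], minlength=h * w)
    return img.reshape(h, w)


# ---------------------------------------------------------------------------
# rendering

def _view_rng(seed: int, station_deg: float, eye: str, illumination: str):
    key = [int(seed) & 0x7FFFFFFF, int(round(station_deg * 1000.0)) % 360000,
           0 if eye == "left" else 1, 0 if illumination == "contour" else 1]
    return np.random.default_rng(key)


def _render_scene(spec: PhantomSpec, cam: CameraModel, rig: RotationalRig,
                  station_deg: float, eye: str, illumination: str,
                  rectified_pose: bool):
    r_wc, centre = camera_pose(rig, station_deg, eye, rectified=rectified_pose)
    cast = _raycast(spec, cam, r_wc, centre)
    hit = cast["hit"]
    h, w = hit.shape
    # Lambertian-ish shading toward the camera
    view = centre[None, None, :] - cast["points"]
    with np.errstate(invalid="ignore"):
        view /= np.linalg.norm(view, axis=-1, keepdims=True)
        shade = np.clip(np.einsum("ijk,ijk->ij", cast["normals"], view), 0.0, 1.0)
    shade = np.where(hit, shade, 0.0)

    samples = _vessel_samples(spec)
    vis = None
    proj = None
    if samples is not None:
        view_dir = centre[None, :] - samples["anchor"]
        view_dir /= np.linalg.norm(view_dir, axis=1, keepdims=True)
        vis = np.einsum("ij,ij->i", samples["normal"], view_dir) > 0.1
        u, v, z = project_points(samples["pos"], cam, r_wc, centre)
        vis &= z > 0
        proj = (u, v, z)

    intensity = np.zeros((h, w))
    if illumination == "contour":
        sampler = _texture_sampler(spec)
        albedo = np.zeros((h, w))
        albedo[hit] = sampler(cast["s_along"][hit], cast["s_around"][hit])
        intensity = albedo * (0.25 + 0.75 * shade)
        if spec.imprint_vessels and samples is not None and vis.any():
            us, vs, zs = project_points(samples["anchor"], cam, r_wc, centre)
            ok = vis & (zs > 0)
            mm_per_px = zs[ok] / cam.focal_px
            r_px = samples["radius"][ok] / mm_per_px
            sig = np.sqrt(spec.base_blur_px ** 2 + (0.6 * r_px) ** 2)
            paint = _splat((h, w), us[ok], vs[ok], np.ones(ok.sum()), sig,
                           0.15, mm_per_px)
            intensity *= 1.0 - 0.5 * np.clip(paint, 0.0, 1.0)
    elif illumination == "fluorescence":
        intensity = spec.body_glow * shade
        if samples is not None and vis.any():
            u, v, z = proj
            ok = vis
            mm_per_px = z[ok] / cam.focal_px
            r_px = samples["radius"][ok] / mm_per_px
            dep = samples["depth"][ok]
            sig = np.sqrt(spec.base_blur_px ** 2 +
                          (spec.blur_px_per_mm * np.abs(dep)) ** 2 +
                          (0.5 * r_px) ** 2)
            mod = 0.7 + 0.3 * np.sin(2 * np.pi * samples["arclen"][ok] / 2.5 +
                                     samples["phase"][ok])
            amp = np.exp(dep / spec.attenuation_length_mm) * mod
            intensity += _splat((h, w), u[ok], v[ok], amp, sig, 0.15, mm_per_px)
    else:
        raise ValueError(f"unknown illumination '{illumination}'")

    # ground truth
    centerline = np.zeros((h, w), dtype=bool)
    vessel_z = np.full((h, w), np.nan, dtype=np.float32)
    if samples is not None and vis is not None and vis.any():
        u, v, z = proj
        cu = np.rint(u[vis]).astype(np.int64)
        cv = np.rint(v[vis]).astype(np.int64)
        inb = (cu >= 0) & (cu < w) & (cv >= 0) & (cv < h)
        cu, cv, zz = cu[inb], cv[inb], z[vis][inb].astype(np.float32)
        centerline[cv, cu] = True
        flat = cv * w + cu
        vz = np.full(h * w, np.inf, dtype=np.float32)
        np.minimum.at(vz, flat, zz)
        vessel_z = np.where(np.isfinite(vz), vz, np.nan).reshape(h, w)
    gt = GroundTruth(depth_map_mm=cast["z"].astype(np.float32),
                     vessel_centerline_mask=centerline,
                     vessel_depth_map_mm=vessel_z,
                     station_deg=station_deg, eye=eye, rectified=rectified_pose)
    return intensity, gt


def render_view(spec: PhantomSpec, cam: CameraModel, rig: RotationalRig,
                station_deg: float, eye: str, seed: int,
                illumination: str = "contour", noise: bool = True,
                rectified_pose: bool = False) -> tuple[np.ndarray, GroundTruth]:
    """Render one eye view as a 16-bit image plus its ground truth.

    The eye applies a stage rotation of +theta (left) or -theta (right)
    relative to ``station_deg`` (normalized into [0, 360)).  With
    ``rectified_pose=True`` the scene is imaged by the de-rotated virtual
    camera of the parallel rig instead (useful as warp-free ground truth).
    """
    station_deg = float(np.mod(station_deg, 360.0))
    intensity, gt = _render_scene(spec, cam, rig, station_deg, eye,
                                  illumination, rectified_pose)
    expected = np.clip(intensity, 0.0, None) * spec.photon_scale
    if noise:
        rng = _view_rng(seed, station_deg, eye, illumination)
        counts = rng.poisson(expected).astype(np.float64)
        counts += rng.normal(0.0, spec.read_noise_counts, size=counts.shape)
    else:
        counts = expected
    image = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return image, gt


def render_acquisition(spec: PhantomSpec, cam: CameraModel, rig: RotationalRig,
                       seed: int, illumination: str = "contour",
                       noise: bool = True) -> list[tuple[np.ndarray, GroundTruth]]:
    """One left and one right view per rig station, in station order.

    Eight stations therefore produce sixteen images.
    """
    out = []
    for station in rig.station_angles_deg:
        for eye in ("left", "right"):
            out.append(render_view(spec, cam, rig, station, eye, seed,
                                   illumination=illumination, noise=noise))
    return out


def ground_truth_view(spec: PhantomSpec, cam: CameraModel, rig: RotationalRig,
                      station_deg: float, eye: str = "left",
                      rectified: bool = True) -> GroundTruth:
    """Analytic ground truth for a (by default rectified) camera pose,
    computed by raycasting rather than by warping a raw-view truth."""
    _, gt = _render_scene(spec, cam, rig, float(np.mod(station_deg, 360.0)),
                          eye, "fluorescence" if spec.vessel_pattern else
                          "contour", rectified)
    return gt
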