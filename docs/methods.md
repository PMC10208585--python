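# Methods

This note documents the models behind `rotastereo`, the choices made where
the design was genuinely open, and what the synthetic experiments do and
do not demonstrate.

## Rotational stereo geometry

A single pinhole camera (focal length `f`, pixel pitch `p`, principal
point at the sensor centre) views a rotary stage whose vertical axis sits
at distance `D` on the optical axis. Rotating the stage by ±θ is
equivalent to two virtual cameras on the rotation circle, separated by the
chord `b = 2 D sin θ`, each verged on the stage centre. De-rotating each
view by ∓θ about the stage axis — on the image, the homography
`K R_y(±θ) K⁻¹` — yields a parallel rectified pair: both virtual eyes sit
at `(∓b/2, 0, D cos θ)` in the station frame with parallel optical axes,
so corresponding points share image rows exactly and

```
Z = b · f / (d · p)          (triangulation; d in pixels)
Dr = Z² / (f · b) · Δp       (depth resolution for matching error Δp, mm)
```

`Z` is perpendicular depth in the rectified frame. The two formulas are
first-order consistent: perturbing `Z` by ε changes the forward-model
disparity by the amount `Dr` maps back to ε (verified to 5% in tests).

The rig accepts either an explicit baseline or a half-angle; when both are
given the explicit baseline wins. That matters because the nominal
hardware values (D = 440 mm, b = 60 mm, θ = 3.5°) are mutually
inconsistent — 2·440·sin 3.5° ≈ 53.7 mm — so both routes are exposed and
the nominal experiments fix `b = 60 mm` and derive θ ≈ 3.91°. Similarly,
the depth-resolution model at the nominal rig parameters evaluates to
0.369 mm, not the frequently quoted 0.3 mm; the formula is exposed as-is
and no constant is forced.

Conventions: images are row-major with the origin top-left; the camera
frame is x-right/y-down/z-forward; the stage frame is right-handed with +y
the rotation axis (up) and +z from stage toward camera. Disparity is
`x_left − x_right`, positive in front of the camera; non-positive
disparities are masked invalid rather than propagated as infinite depth.

## Semi-global matching

Matching cost options per pixel and candidate disparity:

* `census` (default for lamp-lit surfaces): Hamming distance of 5×5
  census descriptors on 8-bit-normalized images. Robust to radiometric
  differences; its cost profile is piecewise-linear, so subpixel estimates
  carry a small (~0.1 px) systematic bias.
* `ssd` (default for fluorescence): 7×7 windowed squared difference
  (scaled by 1/64). The minimum is locally quadratic on smooth Gaussian
  vessel profiles, which makes the parabolic subpixel step essentially
  unbiased (measured ~0.05 px RMS on sinusoid planes).
* `sad`: windowed absolute difference, kept for completeness.

Aggregation sums the standard SGM recurrence over 8 (or 4) scanline
directions with penalties P1 (unit disparity change) and P2 (larger
jumps); defaults P1 = 10, P2 = 120 for census and P1 = 4, P2 = 60 for the
rescaled SSD cost. The implementation sweeps whole rows/columns at a time
(vectorised over pixels × disparities); a single path on a single row is
tested for exact equality against a brute-force enumeration over all
disparity sequences.

Selection is winner-take-all (ties to the smaller disparity), parabolic
subpixel refinement clamped to (−0.5, 0.5), then a left–right consistency
check with a 1 px tolerance. The right-reference disparity is obtained by
re-indexing the left-reference aggregated volume (`A_R(r,c,d) =
A_L(r,c+d,d)`) rather than running a second aggregation — half the cost,
standard practice, and adequate for occlusion detection. Two details
matter for correctness:

* candidates whose matching column falls outside the other image are
  excluded from WTA and flatness decisions by construction (not via a
  sentinel magnitude);
* flatness (all in-bounds costs equal → ambiguous pixel) is detected on
  the **raw** cost volume: aggregation deliberately propagates structure
  from textured neighbours into textureless regions and would otherwise
  hide genuinely ambiguous zero-texture background.

The disparity search window is derived from the rig geometry and the
scene's known radial extent (e.g. [232, 256] px for the cylinder at the
nominal rig) rather than scanning from zero; this is purely a speed/
robustness choice and is config-overridable.

## Vessel enhancement

Scale-normalized Hessian eigenvalues (`σ²`-weighted Gaussian derivatives,
|λ1| ≤ |λ2|) feed the standard bright-on-dark tubularity score

```
v = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),   v = 0 where λ2 > 0
R_B = λ1/λ2,  S = √(λ1²+λ2²)
```

maximized over scales {1, 2, 3, 4} px with β = 0.5. `c` defaults to half
the maximum `S` per scale, which makes the score exactly invariant to
positive affine intensity changes. One numerical subtlety: scipy's
truncated second-derivative Gaussian kernels have a small nonzero DC gain,
which would give constant images a spurious response; the implementation
cancels it explicitly, restoring `v ≡ 0` on constant input.

For fluorescence, `log_compress=True` applies `log(1+I)` first. Subsurface
vessel signal is attenuated roughly multiplicatively with depth; in log
space that attenuation becomes an additive offset the Hessian ignores, so
vessels at −5 mm segment as reliably as superficial ones (without it, the
global `c` calibration is dominated by bright shallow vessels and deep
ones fall below threshold). Segmentation thresholds the score (default
0.2), removes components below 30 px, and can report nested intensity
levels for a list of thresholds.

Enhancement is applied as a mask **after** matching by default (the
matcher sees the raw rectified fluorescence image); the pre-matching hook
exists but the smooth vessel profiles match well without it.

## Synthetic scenes

The generator renders analytic surfaces through the exact pinhole model by
per-pixel raycasting, so ground truth (depth per pixel, vessel centreline
pixels and their depths) is exact rather than rasterised:

* **cylinder** (contour validation): vertical circular cylinder, radius
  20 mm, height 50 mm, carrying three helical vessel stripes of radius
  0.4 mm on its surface; under "contour" illumination the surface has a
  seeded two-octave random albedo texture (correlation lengths ~0.3 and
  ~1.5 mm) with Lambertian-style shading, and the vessel pattern is
  imprinted as darker paint.
* **mouse_body** (vessel-depth validation): a vertical elliptical
  cylinder (semi-axes 14 × 9 mm, height 60 mm) standing in for a small
  animal; a trunk-and-branches vessel tree whose segment depths step from
  0 to −5 mm below the surface, covering the claimed imaging-depth span.
* **plane**: fronto-parallel textured plane (random or sinusoid texture),
  used as a calibration-style fixture.

Fluorescence rendering splats vessel centreline samples as Gaussian
tubes with intensity `exp(depth/ℓ)` (ℓ = 2 mm) and blur
`σ = √(σ₀² + (0.5·|depth|)² + (0.5·r_px)²)` px, over a faint (3%) body
glow; a smooth sinusoidal intensity modulation along each vessel emulates
the texture real vessels show and anchors the correspondence search along
epipolar-parallel segments. Photon counts are Poisson at a peak scale of
20 000 with 3-count Gaussian read noise — a high-SNR regime consistent
with bright NIR-II contrast agents. The blur/attenuation model is a
deliberate parameterization, not radiative transfer: passing tests show
the *reconstruction chain* is correct and meets its error budgets under
realistic image statistics, not that tissue optics are modelled.

All randomness (textures, tree jitter, noise) derives from integer seeds;
a fixed seed reproduces images bit-for-bit.

## Fusion and co-registration

Valid depth pixels back-project through the rectified-left camera and move
into the stage frame by a rigid transform: the fixed axis alignment
(image y-down → stage y-up, opposing z), translation by the known eye
position `(−b/2, 0, D cos θ)`, and rotation by −station about the vertical
axis. No ICP refinement is applied by default — the mechanical stage *is*
the registration, and on the nominal geometry the 8 per-station clouds
agree to well under the depth resolution. Merging concatenates clouds and
voxel-downsamples (centroid per occupied voxel; 0.1–0.2 mm default).

The cylinder fit minimizes point-to-axis distance minus radius over the
axis foot point, two small tilt angles and the radius (soft-L1 loss
against matching outliers), initialized vertical; height is the
percentile-trimmed (0.1%) extent along the fitted axis, which discards
stray outliers at the cost of a few hundredths of a millimetre of bias.

Contour/vessel co-registration assigns each vessel point the signed
distance to the nearest contour point along the local surface normal
(PCA over k = 20 neighbours, oriented away from the stage axis); negative
means below the surface. In the single-station workflow the same quantity
is computed per pixel as `z_surface − z_vessel` between the lamp-lit and
fluorescence depth maps of one station, after NaN-aware Gaussian smoothing
(σ = 4 px) of the reference surface — skin is smooth at the millimetre
scale, so smoothing suppresses matching noise in the reference without
biasing gentle curvature.

## Validation experiments and problem sizes

* **Cylinder recovery**: 8 stations × 2 eyes at 640×512, full chain
  (render → rectify → census SGM → triangulate → fuse → fit). Recovered
  radius is within ~0.02 mm of the nominal 20 mm and height within
  ~0.2 mm of 50 mm; runs in ~15 s on one CPU.
* **Vessel depth recovery**: one station, lamp + fluorescence pairs at
  640×512; RMSE of depth-below-surface over ground-truth centreline
  pixels is ~0.24 mm (stable across seeds), inside the 0.3 mm target.
  About 78% of centreline pixels survive all validity gates; coverage is
  lowest for the deepest (−4 to −5 mm) segments, where blur and
  attenuation are strongest — reported, not hidden.

## Known limitations

* The scattering model (Gaussian blur growing linearly with depth) and
  the ±θ-only rectification (small-angle, vertical-axis) are valid for
  the geometry emulated here (θ ≲ 7°, mechanically aligned axis); neither
  generalizes to wide-baseline stereo or strongly scattering media.
* Census subpixel bias (~0.1 px ≈ 0.18 mm at the nominal rig) is the
  dominant systematic in contour depth; the SSD path avoids it for
  fluorescence but is less robust to radiometric mismatch.
* Lens distortion, camera intrinsics calibration, volumetric (3D)
  vesselness, vessel diameter quantification and non-rigid (breathing)
  motion are out of scope.
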