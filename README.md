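# rotastereo

360-degree rotational-stereo 3D reconstruction for NIR-II fluorescence
angiography, at desk scale.

## The problem

Fluorescence imaging in the second near-infrared window (NIR-II,
1000–1700 nm) sees millimetres-deep vasculature in small animals with low
scattering and almost no autofluorescence. A single NIR-II camera only
yields 2D projections, though. Placing the animal on a rotary stage and
imaging at stage rotations of ±θ turns one camera into a virtual stereo
pair: the two views sit on a chord of the rotation circle with baseline

```
b = 2 D sin θ
```

where `D` is the camera-to-stage-axis distance. Repeating the pair at
stations every 45° around the animal and fusing the per-station depth maps
produces a full 360° model of the body contour (lamp illumination) and of
the blood vessels (laser-excited fluorescence), co-registered in the stage
coordinate system — including the depth of each vessel **below the skin**.

`rotastereo` implements that pipeline end to end on synthetic scenes with
exact ground truth:

* **geometry** — pinhole camera and rotational rig models, epipolar
  rectification by de-rotating each view onto the virtual mid-view,
  triangulation `Z = b·f/d`, and the analytic depth-resolution model
  `Dr = Z²/(f·b)·Δp` for matching error `Δp`.
* **stereo** — a from-scratch semi-global matching (SGM) implementation:
  census / SAD / windowed-SSD costs, 4/8-path aggregation with P1/P2
  penalties, parabolic subpixel refinement, left–right consistency check.
* **vesselness** — multi-scale Hessian (Frangi-type) vessel enhancement
  with eigenvalue analysis, auto-calibrated structureness, segmentation
  into nested intensity levels, and optional log compression that makes
  the response invariant to exponential depth attenuation.
* **phantom** — a synthetic acquisition generator: a cylinder phantom
  (radius 20 mm, height 50 mm) with helical vessel stripes, a mouse-like
  body with a branching vessel tree buried 0 to −5 mm below the surface,
  and textured planes; depth-dependent blur and attenuation, Poisson shot
  noise and Gaussian read noise, all driven by one integer seed.
* **fusion** — back-projection to point clouds, rigid transforms into the
  stage frame using the known station angles, voxel-grid merging,
  least-squares cylinder fitting, and contour/vessel co-registration via
  surface normals.
* **cli / config** — `simulate`, `enhance`, `match`, `reconstruct`,
  `fuse`, `resolution`, `validate` commands over a single YAML
  configuration, writing TIFF maps, ASCII PLY clouds, and JSON manifests.

The nominal rig follows the hardware it emulates: 640×512 InGaAs sensor at
0.02 mm pitch, 35 mm lens, `D = 440 mm`, `b = 60 mm`.

## Worked example

Render a seeded 8-station acquisition of the cylinder phantom, reconstruct
it, and check vessel-depth recovery on the mouse-like scene:

```
$ rotastereo validate --seed 1 --out results/validate
{
  "cylinder": {
    "radius_mm": 19.987034889432433,
    "height_mm": 50.1750827663598,
    "rms_mm": 0.24831877503779004,
    "n_points": 226924,
    "seconds": 12.187856203000138
  },
  "vessel_depth": {
    "rmse_mm": 0.23604358732700348,
    "bias_mm": 0.07429221272468567,
    "n_pixels": 415,
    "coverage": 0.7815442561205274,
    "gt_depth_span_mm": [
      -5.045654296875,
      0.010528564453125
    ],
    "seconds": 2.5410485570000674
  },
  "seed": 1
}
```

Reading: the 16-image 360° acquisition of the radius-20 mm, height-50 mm
cylinder is fused into a 227k-point model whose fitted radius is off by
13 µm and whose surface noise is 0.25 mm RMS; on the mouse-like scene the
depth of vessels buried 0 to −5 mm below the skin is recovered with
0.24 mm RMSE over 415 centreline pixels. The analytic depth-resolution
model puts this in context:

```
$ rotastereo resolution --Z 450 --f 35 --b 40 --dp 0.004 --round 1
0.6
$ rotastereo resolution --Z 440 --f 35 --b 60 --dp 0.004
0.3687619047619048
```

— enlarging the stereo baseline from 40 mm (a two-camera rig) to the 60 mm
afforded by the rotary stage roughly halves the resolvable depth step.

Individual stages are scriptable too:

```
rotastereo simulate --phantom cylinder --stations 8 --seed 1 --out acq
rotastereo reconstruct --in acq --out recon        # writes recon/fused.ply
rotastereo enhance --in acq/fluorescence/000_left.tif --out vesselness.tif
```

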