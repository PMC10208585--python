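"""Multi-scale Hessian vessel enhancement (Frangi-type, 2D, bright-on-dark).

At each analysis scale sigma the image is convolved with Gaussian
second-derivative kernels and the scale-normalized Hessian (sigma^2
weighting) is diagonalized per pixel into eigenvalues |l1| <= |l2|.  For
bright curvilinear structure on a dark background l2 is strongly negative
and l1 near zero, so the tubularity score

    v = exp(-R_B^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2))),  l2 < 0
    v = 0,                                                      l2 >= 0

with blobness R_B = l1/l2 and structure strength S = sqrt(l1^2 + l2^2), is
near 1 on vessel centrelines.  The final score is the maximum over scales.
``c`` defaults to half the maximum S at each scale, which makes the score
exactly invariant to positive affine intensity changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

__all__ = [
    "VesselnessMap",
    "hessian_eigen",
    "vesselness_2d",
    "segment_vessels",
    "DEFAULT_SCALES",
    "DEFAULT_BETA",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_AREA",
]

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
DEFAULT_BETA: float = 0.5
DEFAULT_THRESHOLD: float = 0.2
DEFAULT_MIN_AREA: int = 30


@dataclass
class VesselnessMap:
    """Per-pixel tubularity in [0, 1] with the winning scale and a mask."""

    score: np.ndarray
    scales: tuple[float, ...]
    argmax_scale: np.ndarray
    vessel_mask: np.ndarray
    threshold: float


def hessian_eigen(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the scale-normalized Gaussian Hessian, |l1| <= |l2|."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(image, dtype=np.float64)
    norm = sigma ** 2
    # The truncated discrete second-derivative kernels have a tiny nonzero
    # DC gain, which would give constant images a spurious response; cancel
    # it by subtracting the response of a smoothed copy scaled by the DC
    # gain (the antisymmetric first-derivative kernels are exactly DC-free).
    ones = np.ones_like(img)
    smooth = ndimage.gaussian_filter(img, sigma, mode="nearest")
    hxx = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="nearest")
    hxx = norm * (hxx - smooth * ndimage.gaussian_filter(
        ones, sigma, order=(0, 2), mode="nearest"))
    hyy = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="nearest")
    hyy = norm * (hyy - smooth * ndimage.gaussian_filter(
        ones, sigma, order=(2, 0), mode="nearest"))
    hxy = norm * ndimage.gaussian_filter(img, sigma, order=(1, 1), mode="nearest")
    # closed-form 2x2 symmetric eigendecomposition
    tr_half = 0.5 * (hxx + hyy)
    disc = np.sqrt(np.maximum(0.25 * (hxx - hyy) ** 2 + hxy ** 2, 0.0))
    e_lo = tr_half - disc
    e_hi = tr_half + disc
    swap = np.abs(e_lo) > np.abs(e_hi)
    l1 = np.where(swap, e_hi, e_lo)
    l2 = np.where(swap, e_lo, e_hi)
    return l1, l2


def _frangi_single_scale(image: np.ndarray, sigma: float, beta: float,
                         c: float | None) -> np.ndarray:
    l1, l2 = hessian_eigen(image, sigma)
    s = np.sqrt(l1 ** 2 + l2 ** 2)
    if c is None:
        s_max = float(s.max())
        if s_max <= 0:
            return np.zeros_like(s)
        c = 0.5 * s_max
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
    v = np.exp(-rb2 / (2.0 * beta ** 2)) * (1.0 - np.exp(-s ** 2 / (2.0 * c ** 2)))
    v[l2 > 0] = 0.0  # dark-on-bright structure: not a bright vessel
    v[s == 0] = 0.0
    return v


def vesselness_2d(image: np.ndarray,
                  scales: tuple[float, ...] = DEFAULT_SCALES,
                  beta: float = DEFAULT_BETA,
                  c: float | None = None,
                  threshold: float = DEFAULT_THRESHOLD,
                  log_compress: bool = False) -> VesselnessMap:
    """Multi-scale Frangi-type tubularity score, max over scales.

    ``c=None`` selects half the maximum structure strength S per scale.
    ``log_compress`` applies log(1+I) before filtering: fluorescence from
    subsurface vessels is attenuated multiplicatively with depth, which the
    log turns into an additive offset the Hessian ignores, so deep dim
    vessels score comparably to superficial bright ones.
    """
    if len(scales) == 0:
        raise ValueError("at least one analysis scale required")
    if beta <= 0:
        raise ValueError("beta must be positive")
    img = np.asarray(image, dtype=np.float64)
    if log_compress:
        img = np.log1p(np.clip(img, 0.0, None))
    score = np.zeros(img.shape, dtype=np.float64)
    arg = np.zeros(img.shape, dtype=np.float64)
    for sigma in scales:
        v = _frangi_single_scale(img, sigma, beta, c)
        better = v > score
        arg[better] = sigma
        score = np.where(better, v, score)
    score = np.clip(score, 0.0, 1.0)
    return VesselnessMap(score=score, scales=tuple(scales), argmax_scale=arg,
                         vessel_mask=score >= threshold, threshold=threshold)


def segment_vessels(vmap: VesselnessMap, threshold: float | None = None,
                    levels: tuple[float, ...] | None = None,
                    min_area_px: int = DEFAULT_MIN_AREA
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the tubularity score into a vessel mask.

    Returns ``(mask, level_map)``.  ``level_map`` counts how many of the
    ordered ``levels`` thresholds each pixel exceeds (nested intensity
    levels; 0 outside all).  Connected components smaller than
    ``min_area_px`` are removed, suppressing non-vascular speckle.
    """
    thr = vmap.threshold if threshold is None else threshold
    if not 0 <= thr <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    score = vmap.score
    mask = score >= thr if thr > 0 else score > 0
    if min_area_px > 1:
        comp = label(mask, connectivity=2)
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        mask = (sizes >= min_area_px)[comp]
    level_map = np.zeros(score.shape, dtype=np.int32)
    if levels:
        for lv in sorted(levels):
            level_map += (mask & (score >= lv)).astype(np.int32)
    return mask, level_map
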