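"""Semi-global matching (SGM) for rectified rotational-stereo pairs.

Pipeline: pixelwise matching cost (census Hamming distance, windowed SAD or
windowed SSD) -> directional cost aggregation along 4 or 8 scanline paths
with small/large disparity-change penalties P1/P2 -> winner-take-all with
parabolic subpixel refinement and a left-right consistency check.

The aggregation recurrence along a path direction r is

    L_r(p, d) = C(p, d) + min( L_r(p-r, d),
                               L_r(p-r, d-1) + P1,
                               L_r(p-r, d+1) + P1,
                               min_k L_r(p-r, k) + P2 )
               - min_k L_r(p-r, k)

with L_r = C at pixels without a predecessor.  The implementation sweeps
whole image rows (or columns / shifted rows for diagonal paths) at a time,
so the inner work is vectorised over pixels and disparities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter

from .geometry import DisparityMap

__all__ = [
    "MatchConfig",
    "census_transform",
    "match_cost_volume",
    "sgm_aggregate",
    "disparity_select",
    "match_pair",
]

#: Sentinel cost for disparity candidates that fall outside the right image.
BIG_COST = np.float32(1.0e3)

_PATHS_4 = ((0, 1), (0, -1), (1, 0), (-1, 0))
_PATHS_8 = _PATHS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass(frozen=True)
class MatchConfig:
    """Stereo matching parameters.

    disparity_range is the inclusive integer search window [d_min, d_max]
    in pixels (left minus right column).  Costs: 'census' (Hamming distance
    of binary descriptors, robust on textured surfaces), 'sad'/'ssd'
    (windowed absolute/squared difference; SSD has a locally quadratic
    minimum, so parabolic subpixel refinement is unbiased on smooth
    intensity profiles).  P1/P2 penalize 1-px and larger disparity jumps
    between neighbouring pixels.
    """

    disparity_range: tuple[int, int] = (0, 64)
    cost: str = "census"
    census_window: int = 5
    P1: float = 10.0
    P2: float = 120.0
    n_paths: int = 8
    lr_consistency_px: float | None = 1.0
    subpixel: bool = True

    def __post_init__(self):
        d0, d1 = self.disparity_range
        if int(d0) != d0 or int(d1) != d1 or d0 >= d1:
            raise ValueError("disparity_range must be integers with d_min < d_max")
        if self.cost not in ("census", "sad", "ssd"):
            raise ValueError(f"unknown cost '{self.cost}'")
        if self.census_window < 3 or self.census_window % 2 == 0:
            raise ValueError("census_window must be odd and >= 3")
        if self.P1 < 0 or self.P2 < self.P1:
            raise ValueError("need 0 <= P1 <= P2")
        if self.n_paths not in (4, 8):
            raise ValueError("n_paths must be 4 or 8")

    @property
    def disparities(self) -> np.ndarray:
        d0, d1 = self.disparity_range
        return np.arange(int(d0), int(d1) + 1)


def _normalize_8bit(image: np.ndarray) -> np.ndarray:
    """Scale an image to [0, 255] float32 (robust to constant images)."""
    img = np.asarray(image, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def census_transform(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Census descriptor: each bit records centre > neighbour.

    Returns uint64 codes; windows up to 9x9 (80 bits would overflow, so the
    window is capped at 7).
    """
    if window % 2 == 0 or window < 3 or window > 7:
        raise ValueError("census window must be odd, in [3, 7]")
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape
    pad = window // 2
    padded = np.pad(img, pad, mode="edge")
    code = np.zeros((h, w), dtype=np.uint64)
    bit = np.uint64(0)
    one = np.uint64(1)
    for dr in range(window):
        for dc in range(window):
            if dr == pad and dc == pad:
                continue
            neigh = padded[dr:dr + h, dc:dc + w]
            code |= (img > neigh).astype(np.uint64) << bit
            bit += one
    return code


def _shift_right_cols(arr: np.ndarray, d: int, fill) -> np.ndarray:
    """arr sampled at column c-d (right-image column for disparity d)."""
    out = np.full_like(arr, fill)
    if d == 0:
        return arr.copy()
    if d > 0:
        out[:, d:] = arr[:, :-d]
    else:
        out[:, :d] = arr[:, -d:]
    return out


def match_cost_volume(left: np.ndarray, right: np.ndarray,
                      cfg: MatchConfig) -> np.ndarray:
    """Per-pixel, per-disparity dissimilarity, shape (H, W, n_disp) float32.

    Disparity d matches left pixel (r, c) with right pixel (r, c-d);
    candidates falling outside the right image get the BIG_COST sentinel.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    if left.shape != right.shape:
        raise ValueError(f"image sizes differ: {left.shape} vs {right.shape}")
    disps = cfg.disparities
    h, w = left.shape
    vol = np.empty((h, w, len(disps)), dtype=np.float32)
    if cfg.cost == "census":
        cl = census_transform(_normalize_8bit(left), cfg.census_window)
        cr = census_transform(_normalize_8bit(right), cfg.census_window)
        for i, d in enumerate(disps):
            shifted = _shift_right_cols(cr, d, np.uint64(0))
            ham = np.bitwise_count(cl ^ shifted).astype(np.float32)
            vol[:, :, i] = ham
    else:
        li = _normalize_8bit(left)
        ri = _normalize_8bit(right)
        size = cfg.census_window
        for i, d in enumerate(disps):
            diff = li - _shift_right_cols(ri, d, 0.0)
            if cfg.cost == "ssd":
                diff = diff * diff
                vol[:, :, i] = uniform_filter(diff, size=size, mode="nearest") / 64.0
            else:  # sad
                vol[:, :, i] = uniform_filter(np.abs(diff), size=size,
                                              mode="nearest") / 8.0
    # out-of-bounds sentinel
    cols = np.arange(w)
    for i, d in enumerate(disps):
        bad = (cols - d < 0) | (cols - d >= w)
        if bad.any():
            vol[:, bad, i] = BIG_COST
    return vol


def _aggregate_direction(cost: np.ndarray, dr: int, dc: int,
                         p1: float, p2: float) -> np.ndarray:
    """One directional SGM pass; see module docstring for the recurrence."""
    if dr == 0:
        swapped = _aggregate_direction(np.swapaxes(cost, 0, 1), dc, 0, p1, p2)
        return np.swapaxes(swapped, 0, 1)
    h, w, nd = cost.shape
    agg = np.empty_like(cost)
    rows = range(h) if dr > 0 else range(h - 1, -1, -1)
    first = True
    for r in rows:
        if first:
            agg[r] = cost[r]
            first = False
            continue
        prev = agg[r - dr]
        if dc != 0:
            prev = np.roll(prev, dc, axis=0)
        m = prev.min(axis=1)
        up = np.empty_like(prev)
        up[:, 1:] = prev[:, :-1]
        up[:, 0] = np.inf
        dn = np.empty_like(prev)
        dn[:, :-1] = prev[:, 1:]
        dn[:, -1] = np.inf
        cand = np.minimum(np.minimum(prev, m[:, None] + p2),
                          np.minimum(up, dn) + p1)
        out = cost[r] + cand - m[:, None]
        if dc != 0:
            edge = 0 if dc > 0 else w - 1
            out[edge] = cost[r][edge]
        agg[r] = out
    return agg


def sgm_aggregate(cost_volume: np.ndarray, cfg: MatchConfig) -> np.ndarray:
    """Sum the directional recurrences over 4 or 8 scanline paths."""
    cost = np.asarray(cost_volume, dtype=np.float32)
    if cost.ndim != 3:
        raise ValueError("cost volume must be (H, W, n_disp)")
    paths = _PATHS_8 if cfg.n_paths == 8 else _PATHS_4
    agg = np.zeros_like(cost)
    for dr, dc in paths:
        agg += _aggregate_direction(cost, dr, dc, cfg.P1, cfg.P2)
    return agg


def _candidate_inbounds(w: int, d_min: int, nd: int,
                        reference: str) -> np.ndarray:
    """(W, n_disp) mask of disparity candidates whose matching column lies
    inside the other image (left reference matches c-d, right matches c+d)."""
    cols = np.arange(w)[:, None]
    disps = d_min + np.arange(nd)[None, :]
    other = cols - disps if reference == "left" else cols + disps
    return (other >= 0) & (other < w)


def _wta(volume: np.ndarray, inb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-all over in-bounds candidates (ties -> smallest
    disparity); pixels whose in-bounds costs are all equal (textureless) or
    that have no in-bounds candidate are flagged flat."""
    masked = np.where(inb[None, :, :], volume, np.inf)
    idx = np.argmin(masked, axis=2)
    hi = np.where(inb[None, :, :], volume, -np.inf).max(axis=2)
    lo = masked.min(axis=2)
    flat = ~np.isfinite(lo) | (hi - lo < 1e-6)
    return idx, flat


def _reindex_to_right(agg: np.ndarray, d_min: int) -> np.ndarray:
    """Right-reference volume A_R(r, c, i) = A_L(r, c + d_min + i, i)."""
    h, w, nd = agg.shape
    cols = np.arange(w)[:, None] + d_min + np.arange(nd)[None, :]
    ok = (cols >= 0) & (cols < w)
    cols_c = np.clip(cols, 0, w - 1)
    out = agg[:, cols_c, np.arange(nd)[None, :]]
    out[:, ~ok] = BIG_COST * agg.shape[2]
    return out


def disparity_select(aggregated: np.ndarray, cfg: MatchConfig,
                     cost_volume: np.ndarray | None = None) -> DisparityMap:
    """WTA disparity with parabolic subpixel refinement and LR check.

    Subpixel offset: delta = (c- - c+) / (2 (c- - 2 c0 + c+)), clamped to
    (-0.5, 0.5); pixels whose cost is flat across all (in-bounds)
    disparities are invalidated, as are pixels failing the left-right
    consistency test |d_L(p) - d_R(p - d_L)| > lr_consistency_px.

    Pass the raw ``cost_volume`` alongside the aggregated one to detect
    flatness before aggregation: path aggregation propagates disparity
    structure from textured neighbours into textureless regions, which
    would otherwise mask genuinely ambiguous (zero-texture) pixels.
    """
    agg = np.asarray(aggregated, dtype=np.float32)
    h, w, nd = agg.shape
    d_min = int(cfg.disparity_range[0])
    inb_left = _candidate_inbounds(w, d_min, nd, "left")
    idx, flat = _wta(agg, inb_left)
    if cost_volume is not None:
        _, flat_raw = _wta(np.asarray(cost_volume, dtype=np.float32), inb_left)
        flat |= flat_raw
    disp = idx.astype(np.float32)
    if cfg.subpixel:
        interior = (idx > 0) & (idx < nd - 1)
        i_c = np.clip(idx, 1, nd - 2)
        rows, cols = np.indices((h, w), sparse=False)
        c0 = agg[rows, cols, i_c]
        cm = agg[rows, cols, i_c - 1]
        cp = agg[rows, cols, i_c + 1]
        den = cm - 2.0 * c0 + cp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (cm - cp) / (2.0 * den)
        delta = np.where(np.abs(den) > 1e-9, delta, 0.0)
        delta = np.clip(delta, -0.5 + 1e-3, 0.5 - 1e-3)
        disp = disp + np.where(interior, delta, 0.0).astype(np.float32)
    disp = disp + d_min
    valid = ~flat
    if cfg.lr_consistency_px is not None:
        agg_r = _reindex_to_right(agg, d_min)
        idx_r, flat_r = _wta(agg_r, _candidate_inbounds(w, d_min, nd, "right"))
        disp_r = (idx_r + d_min).astype(np.float32)
        disp_r[flat_r] = np.nan
        cols = np.arange(w)[None, :]
        c_right = np.rint(cols - disp).astype(np.int64)
        inb = (c_right >= 0) & (c_right < w)
        c_right_c = np.clip(c_right, 0, w - 1)
        rows = np.arange(h)[:, None]
        dr_at = disp_r[rows, c_right_c]
        consistent = inb & np.isfinite(dr_at) & \
            (np.abs(disp - dr_at) <= cfg.lr_consistency_px)
        valid &= consistent
    return DisparityMap(values_px=disp, valid_mask=valid)


def match_pair(left: np.ndarray, right: np.ndarray,
               cfg: MatchConfig | None = None, **overrides) -> DisparityMap:
    """Convenience wrapper: cost volume -> SGM aggregation -> selection."""
    cfg = replace(cfg, **overrides) if cfg is not None else MatchConfig(**overrides)
    vol = match_cost_volume(left, right, cfg)
    agg = sgm_aggregate(vol, cfg)
    return disparity_select(agg, cfg, cost_volume=vol)
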