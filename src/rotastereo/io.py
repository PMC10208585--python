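"""File I/O: 16-bit and float TIFF images, ASCII PLY point clouds, manifests.

Derived float maps (disparity, depth, vesselness) are written as 32-bit
float single-channel TIFF with invalid pixels encoded as NaN.  Point clouds
are exchanged as ASCII PLY with per-point attributes x, y, z, intensity,
depth_mm and station; the writer is local because the attribute set is
non-standard.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_image_tiff", "read_image_tiff",
    "write_float_tiff", "read_float_tiff",
    "write_ply", "read_ply",
    "write_manifest", "read_manifest",
]


def write_image_tiff(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale TIFF."""
    image = np.asarray(image)
    if image.dtype != np.uint16:
        raise ValueError("raw images are written as uint16")
    tifffile.imwrite(str(path), image)


def read_image_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(str(path))
    except Exception as exc:  # corrupt or non-TIFF input
        raise IOError(f"cannot read TIFF image {path}: {exc}") from exc


def write_float_tiff(path, values: np.ndarray,
                     valid_mask: np.ndarray | None = None) -> None:
    """Write a float32 map; pixels outside ``valid_mask`` become NaN."""
    out = np.asarray(values, dtype=np.float32).copy()
    if valid_mask is not None:
        out[~np.asarray(valid_mask, dtype=bool)] = np.nan
    tifffile.imwrite(str(path), out)


def read_float_tiff(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a float map; returns (values, valid_mask) with NaN as invalid."""
    values = read_image_tiff(path).astype(np.float32)
    return values, np.isfinite(values)


# ---------------------------------------------------------------------------
# PLY

_PLY_PROPS = ("x", "y", "z", "intensity", "depth_mm", "station")


def write_ply(path, points_mm: np.ndarray, intensity: np.ndarray | None = None,
              relative_depth_mm: np.ndarray | None = None,
              station_deg: np.ndarray | None = None) -> None:
    """Write an ASCII PLY point cloud with x/y/z plus optional attributes."""
    pts = np.asarray(points_mm, dtype=np.float64).reshape(-1, 3)
    n = len(pts)

    def _col(arr, fill):
        if arr is None:
            return np.full(n, fill, dtype=np.float64)
        return np.asarray(arr, dtype=np.float64).reshape(-1)

    cols = np.column_stack([
        pts,
        _col(intensity, 0.0),
        _col(relative_depth_mm, np.nan),
        _col(station_deg, -1.0),
    ])
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    header += [f"property float {p}" for p in _PLY_PROPS]
    header.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, cols, fmt="%.6f")


def read_ply(path) -> dict[str, np.ndarray]:
    """Read an ASCII PLY written by :func:`write_ply`.

    Returns a dict with ``points_mm`` (N,3) and the extra attribute columns.
    """
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise IOError(f"{path} is not a PLY file")
        props: list[str] = []
        n = 0
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: truncated PLY header")
            line = line.strip()
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n, ndmin=2) if n else np.empty((0, len(props)))
    out = {"points_mm": data[:, :3]}
    for i, p in enumerate(props[3:], start=3):
        out[p] = data[:, i]
    return out


# ---------------------------------------------------------------------------
# manifests

def write_manifest(path, payload: dict) -> None:
    """Machine-readable run manifest (JSON key/value sidecar)."""
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
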