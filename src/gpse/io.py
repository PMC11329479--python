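"""File readers/writers: Mueller CSV, 16-page Mueller TIFF, intensity
frames, parameter maps and PLY mesh export.

On-disk conventions
-------------------
* Mueller matrix: comma-delimited text, 4 rows x 4 columns, row-major,
  plain decimals at full round-trip precision (17 significant digits).
* Mueller image: 16-page 32-bit-float TIFF, pages ordered
  m11, m12, m13, m14, m21, ..., m44 (recorded in the TIFF description tag).
* Intensity frames: 30-page TIFF or a delimited text file with one row per
  frame (single-pixel mode: one value per row).
* GPSE mesh: ASCII PLY; the first vertex element holds the projected cloud
  colored by source-state latitude (green near the north pole of the
  Poincare sphere, blue near the south), a second element holds points on
  the fitted ellipsoid surface.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .core import MuellerImage, MuellerMatrix
from .engine import Ellipsoid, GPSEPointCloud
from .errors import FormatError

__all__ = [
    "read_mueller_csv",
    "write_mueller_csv",
    "read_mueller_tiff",
    "write_mueller_tiff",
    "read_intensity_frames",
    "write_intensity_frames",
    "write_parameter_map",
    "export_gpse_mesh",
    "write_provenance",
]

PLANE_ORDER = "m11,m12,m13,m14,m21,m22,m23,m24,m31,m32,m33,m34,m41,m42,m43,m44"


def read_mueller_csv(path) -> MuellerMatrix:
    """Read a 4x4 delimited-text Mueller matrix (no implicit normalization)."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric Mueller CSV ({exc})") from exc
    if arr.shape != (4, 4):
        raise FormatError(
            f"{path}: expected a 4x4 grid, got {arr.shape[0]} rows x "
            f"{arr.shape[1]} columns"
        )
    return MuellerMatrix(arr)


def write_mueller_csv(m: MuellerMatrix, path) -> None:
    np.savetxt(path, m.m, delimiter=",", fmt="%.17g")


def read_mueller_tiff(path) -> MuellerImage:
    """Read a 16-page Mueller image TIFF (planes ordered m11..m44)."""
    path = Path(path)
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 16:
        raise FormatError(
            f"{path}: expected a 16-page TIFF, got shape {planes.shape}"
        )
    return MuellerImage.from_planes(planes.astype(float))


def write_mueller_tiff(img: MuellerImage, path) -> None:
    tifffile.imwrite(
        path,
        img.to_planes().astype(np.float32),
        description=f"plane order: {PLANE_ORDER}",
    )


def read_intensity_frames(path) -> np.ndarray:
    """Read DRR intensity frames from a multi-page TIFF or text file.

    Returns shape (n_frames,) for single-value rows / single-pixel pages, or
    (n_frames, H, W) for image stacks.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 2 and 1 in arr.shape:
            arr = arr.reshape(arr.shape[0] * arr.shape[1])
        return arr
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity table ({exc})") from exc
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    return arr


def write_intensity_frames(intensities, path) -> None:
    np.savetxt(path, np.asarray(intensities), delimiter=",", fmt="%.17g")


def write_parameter_map(arr: np.ndarray, path) -> None:
    """Write a scalar parameter map as a single-page 32-bit TIFF."""
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def _latitude_rgb(lat: float):
    """Green at the north pole -> blue at the south pole."""
    t = (lat + np.pi / 2) / np.pi
    return int(round(255 * t)), int(round(255 * (1 - t)))


def export_gpse_mesh(cloud: GPSEPointCloud, ellipsoid: Ellipsoid, path) -> None:
    """Write the projected cloud + fitted ellipsoid surface as ASCII PLY.

    Cloud vertices carry per-vertex RGB encoding the *incident* state's
    latitude.  A degenerate (collapsed) ellipsoid produces a point-only
    file with a warning.
    """
    path = Path(path)
    pts = np.asarray(cloud.points)
    lats = [s.latitude for s in cloud.states]
    degenerate = ellipsoid.degenerate
    if degenerate:
        warnings.warn(
            "degenerate ellipsoid: writing point-only PLY without an "
            "ellipsoid surface element",
            stacklevel=2,
        )
        surface = np.empty((0, 3))
    else:
        surface = ellipsoid.surface_points()
    lines = [
        "ply",
        "format ascii 1.0",
        "comment GPSE point cloud colored by incident-state latitude",
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        f"element ellipsoid_vertex {len(surface)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    for p, lat in zip(pts, lats):
        g, b = _latitude_rgb(lat)
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} 0 {g} {b}")
    for p in surface:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    path.write_text("\n".join(lines) + "\n")


def write_provenance(path, inputs: dict, config: dict, seed=None) -> None:
    """Emit the JSON provenance block accompanying every CLI run."""
    from . import __version__

    block = {
        "tool": "gpse",
        "version": __version__,
        "inputs": inputs,
        "config": config,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(block, indent=2, default=str) + "\n")
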