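"""Global-Polarization Stokes Ellipsoid (GPSE) construction and parameters.

The GPSE of a medium is obtained by sending *every* fully polarized state
through its Mueller matrix and plotting the exiting states in the Poincare
ball, each normalized by its own exiting intensity so that the distance of a
projected point from the origin is the exiting degree of polarization.  For
a physical medium the image of the unit sphere under this projective map is
exactly a quadric, generically an ellipsoid.  Three scalars summarize it:

* ``V = cbrt(a * b * c)`` - the equivalent-volume radius; 1 for a perfectly
  polarization-maintaining medium, 0 when the ellipsoid collapses to a
  point (complete depolarization).
* ``E = sqrt(1 - (b^2 + c^2) / (2 a^2))`` - eccentricity; 0 for a sphere,
  growing with anisotropy (birefringence, fiber order, fiber content).
* ``D† = 3 ||center|| / (a + b + c)`` - displacement of the ellipsoid
  center, normalized by the mean semi-axis to suppress pure-depolarization
  scaling; driven mainly by diattenuation / polarizance.

Here ``a >= b >= c >= 0`` are the semi-axis lengths of the fitted
ellipsoid (written a, b-dagger, c in the polarimetry literature).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MuellerImage, MuellerMatrix, normalize_mueller, physical_realizability
from .errors import (
    FitError,
    InsufficientDataError,
    ParameterError,
    ProjectionError,
)

__all__ = [
    "StateSample",
    "GPSEPointCloud",
    "Ellipsoid",
    "GPSEParams",
    "sample_full_polarization_states",
    "gpse_point_cloud",
    "fit_gpse_ellipsoid",
    "gpse_parameters",
    "gpse_axis_orientation",
    "region_mean_mueller",
    "gpse_map",
    "optimal_incident_state",
    "gpse_from_mueller",
    "DEGENERACY_TOL",
]

#: semi-axes (and point-cloud spreads) below this are treated as collapsed.
DEGENERACY_TOL = 1e-9

_CANONICAL6 = {
    "H": (1.0, 0.0, 0.0),  # 0 deg linear
    "V": (-1.0, 0.0, 0.0),  # 90 deg linear
    "P": (0.0, 1.0, 0.0),  # 45 deg linear
    "M": (0.0, -1.0, 0.0),  # 135 deg linear
    "R": (0.0, 0.0, 1.0),  # right circular (north pole)
    "L": (0.0, 0.0, -1.0),  # left circular (south pole)
}


@dataclass(frozen=True)
class StateSample:
    """A fully polarized incident state: a unit direction on the Poincare
    sphere, its latitude (for rendering) and an optional canonical label."""

    direction: np.ndarray
    latitude: float
    label: Optional[str] = None

    def stokes(self) -> np.ndarray:
        """Unit-intensity Stokes vector (1, s1, s2, s3)."""
        return np.concatenate(([1.0], self.direction))


@dataclass
class GPSEPointCloud:
    """Projected output states (N x 3, Poincare coordinates) paired with
    their source incident states."""

    points: np.ndarray
    states: Sequence[StateSample]

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def radii(self) -> np.ndarray:
        """Per-point distance from the origin (= exiting DoP)."""
        return np.linalg.norm(self.points, axis=1)


@dataclass
class Ellipsoid:
    """A fitted ellipsoid: center, ordered semi-axes ``a >= b >= c >= 0``,
    a proper rotation whose columns are the long/middle/short axis
    directions, and the RMS fit residual."""

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray
    fit_residual: float

    @property
    def degenerate(self) -> bool:
        return bool(self.semi_axes.min() < DEGENERACY_TOL)

    def surface_points(self, n_u: int = 24, n_v: int = 12) -> np.ndarray:
        """Points on the ellipsoid surface (u-v sphere grid), for export."""
        u = np.linspace(0, 2 * np.pi, n_u, endpoint=False)
        v = np.linspace(0, np.pi, n_v)
        uu, vv = np.meshgrid(u, v)
        sph = np.stack(
            [np.cos(uu) * np.sin(vv), np.sin(uu) * np.sin(vv), np.cos(vv)], axis=-1
        ).reshape(-1, 3)
        return self.center + (sph * self.semi_axes) @ self.orientation.T


@dataclass
class GPSEParams:
    """The three GPSE descriptors plus a degeneracy flag.

    ``E`` and ``D_dagger`` are NaN when their defining ratios are 0/0
    (fully collapsed ellipsoid)."""

    V: float
    E: float
    D_dagger: float
    degenerate: bool


def sample_full_polarization_states(n: int = 2000, method: str = "fibonacci"):
    """Deterministic unit-sphere sampling of fully polarized states.

    ``fibonacci`` - golden-spiral lattice, near-uniform (default);
    ``latlong`` - latitude-longitude grid (for Fig-style rendering bands);
    ``canonical6`` - exactly the six axis intersections (0/45/90/135 deg
    linear and the two circular states).
    """
    if method == "canonical6":
        out = []
        for label, d in _CANONICAL6.items():
            d = np.asarray(d)
            out.append(StateSample(d, float(math.asin(d[2])), label))
        return out
    if n < 6:
        raise ParameterError(f"need at least 6 states, got {n}")
    if method == "fibonacci":
        i = np.arange(n)
        z = 1.0 - (2.0 * i + 1.0) / n
        phi = i * math.pi * (3.0 - math.sqrt(5.0))
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    elif method == "latlong":
        n_lat = max(3, int(round(math.sqrt(n / 2))))
        n_lon = max(4, int(math.ceil(n / n_lat)))
        lat = np.linspace(-math.pi / 2, math.pi / 2, n_lat)
        lon = np.linspace(0, 2 * math.pi, n_lon, endpoint=False)
        gl, gn = np.meshgrid(lat, lon, indexing="ij")
        dirs = np.stack(
            [np.cos(gl) * np.cos(gn), np.cos(gl) * np.sin(gn), np.sin(gl)], axis=-1
        ).reshape(-1, 3)
    else:
        raise ParameterError(f"unknown sampling method {method!r}")
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return [
        StateSample(d, float(math.asin(np.clip(d[2], -1, 1)))) for d in dirs
    ]


def _project_directions(m: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Project unit directions through a Mueller matrix; returns N x 3
    Poincare points (output Stokes normalized by its own S0')."""
    s0 = m[0, 0] + dirs @ m[0, 1:]
    if np.any(s0 <= 0):
        k = int(np.argmin(s0))
        raise ProjectionError(
            f"non-positive exiting intensity S0' = {s0[k]:.3g} for incident "
            f"direction {dirs[k]}"
        )
    pts = (m[1:, 0][None, :] + dirs @ m[1:, 1:].T) / s0[:, None]
    return pts


def gpse_point_cloud(
    m: MuellerMatrix, states: Sequence[StateSample], check_physical: bool = True
) -> GPSEPointCloud:
    """Project every incident state through ``m`` into the Poincare ball.

    For each unit direction s the incident Stokes vector is ``(1, s)``; the
    exiting vector ``S' = M (1, s)`` is mapped to ``(S1', S2', S3') / S0'``
    so each point's radius is the exiting degree of polarization.
    """
    if len(states) == 0:
        raise ParameterError("states must be nonempty")
    if check_physical and not physical_realizability(m).is_physical:
        warnings.warn(
            "Mueller matrix fails the coherency-eigenvalue physicality test; "
            "projected points may leave the Poincare ball",
            stacklevel=2,
        )
    dirs = np.stack([s.direction for s in states])
    pts = _project_directions(m.m, dirs)
    return GPSEPointCloud(points=pts, states=list(states))


def _canonical_orientation(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign/handedness: first two axis directions point
    toward +S1 (then +S2, +S3 on ties); the third is their cross product,
    making the rotation proper."""
    out = vecs.copy()
    for k in range(2):
        v = out[:, k]
        for comp in range(3):
            if abs(v[comp]) > 1e-12:
                if v[comp] < 0:
                    out[:, k] = -v
                break
    out[:, 2] = np.cross(out[:, 0], out[:, 1])
    return out


def _order_axes(semi: np.ndarray, vecs: np.ndarray):
    order = np.argsort(semi)[::-1]
    return semi[order], _canonical_orientation(vecs[:, order])


def _fit_full_quadric(pts: np.ndarray):
    """Least-squares general quadric through the points (unit-norm
    coefficient vector); returns (Q 3x3, b 3-vector, j scalar)."""
    x, y, z = pts.T
    design = np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    A, B, C, D, E, F, G, H, I, J = coef
    q = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    return q, np.array([G, H, I]), J, coef


def _geometric_residual(pts: np.ndarray, coef: np.ndarray) -> float:
    """RMS of |F(p)| / ||grad F(p)|| - a first-order point-to-surface
    distance, invariant to the quadric's overall scale."""
    x, y, z = pts.T
    A, B, C, D, E, F, G, H, I, J = coef
    f = (
        A * x * x + B * y * y + C * z * z
        + D * x * y + E * x * z + F * y * z
        + G * x + H * y + I * z + J
    )
    gx = 2 * A * x + D * y + E * z + G
    gy = 2 * B * y + D * x + F * z + H
    gz = 2 * C * z + E * x + F * y + I
    gn = np.sqrt(gx * gx + gy * gy + gz * gz)
    gn = np.where(gn < 1e-300, 1.0, gn)
    return float(np.sqrt(np.mean((f / gn) ** 2)))


def fit_gpse_ellipsoid(cloud: GPSEPointCloud) -> Ellipsoid:
    """Fit the (possibly degenerate) ellipsoid through a projected cloud.

    The noise-free cloud lies exactly on a quadric, so a direct algebraic
    least-squares fit recovers it to machine precision.  Directions in
    which the cloud has collapsed below ``DEGENERACY_TOL`` get semi-axis 0
    and the fit proceeds in the remaining subspace (ellipse, segment or
    point).
    """
    pts = np.asarray(cloud.points, dtype=float)
    if pts.shape[0] < 9:
        raise InsufficientDataError(
            f"need at least 9 points to fit an ellipsoid, got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    spread = s / math.sqrt(pts.shape[0])
    ndeg = int(np.sum(spread < DEGENERACY_TOL))
    rank = 3 - ndeg

    if rank == 3:
        q, b, j, coef = _fit_full_quadric(pts)
        wq, vecs = np.linalg.eigh(q)
        if wq.min() * wq.max() <= 0:
            raise FitError(
                "fitted quadric is not an ellipsoid (quadratic-form "
                f"eigenvalues {wq}); residual of general fit "
                f"{_geometric_residual(pts, coef):.3g}"
            )
        center = -0.5 * np.linalg.solve(q, b)
        k = float(center @ q @ center) - j
        ratios = k / wq
        if np.any(ratios <= 0):
            raise FitError(
                "fitted quadric is an imaginary ellipsoid; residual "
                f"{_geometric_residual(pts, coef):.3g}"
            )
        semi = np.sqrt(ratios)
        semi, vecs = _order_axes(semi, vecs)
        return Ellipsoid(
            center=center,
            semi_axes=semi,
            orientation=vecs,
            fit_residual=_geometric_residual(pts, coef),
        )

    # Degenerate path.  When the cloud collapses in one or more directions
    # the projected set is a *filled* ellipse / segment / point (the sphere
    # maps many-to-one), so no boundary quadric passes through all points.
    # The collapsed semi-axes are set to 0 and the surviving ones are
    # measured as half-extents along the principal directions - exact for a
    # point, and accurate to the sampling density of the incident sphere
    # otherwise (see the methods note).
    axes = vt.T  # columns: principal directions, spread-descending
    if rank == 0:
        return Ellipsoid(
            center=centroid,
            semi_axes=np.zeros(3),
            orientation=_canonical_orientation(np.eye(3)),
            fit_residual=float(np.sqrt(np.mean(np.sum(centered**2, axis=1)))),
        )
    t = centered @ axes
    half = 0.5 * (t.max(axis=0) - t.min(axis=0))
    mid = 0.5 * (t.max(axis=0) + t.min(axis=0))
    semi = np.where(np.arange(3) < rank, half, 0.0)
    center = centroid + axes @ np.where(np.arange(3) < rank, mid, 0.0)
    order = np.argsort(semi)[::-1]
    vecs = _canonical_orientation(axes[:, order])
    resid = float(
        np.sqrt(np.mean(np.sum((t[:, rank:]) ** 2, axis=1)))
    )
    return Ellipsoid(
        center=center, semi_axes=semi[order], orientation=vecs, fit_residual=resid
    )


def gpse_parameters(e: Ellipsoid) -> GPSEParams:
    """The V / E / D-dagger descriptors of a fitted ellipsoid.

    ``V = cbrt(a b c)``; ``E = sqrt(1 - (b^2 + c^2) / (2 a^2))``;
    ``D† = 3 ||center|| / (a + b + c)``.  Collapsed ellipsoids set the
    degenerate flag; ratios that become 0/0 are reported as NaN.

    Because E is a square root of axis differences it is ill-conditioned
    near a sphere: machine-precision axis noise of ~1e-15 would inflate to
    E ~ 1e-8.  Semi-axes agreeing within a relative 1e-12 are therefore
    treated as equal (this cannot mask any genuine eccentricity above
    ~1e-6).
    """
    a, b, c = e.semi_axes
    degenerate = e.degenerate
    v = float(np.cbrt(max(a * b * c, 0.0)))
    if a < DEGENERACY_TOL:
        ecc = math.nan
    elif (a - c) <= 1e-12 * a:
        ecc = 0.0
    else:
        ecc = math.sqrt(max(1.0 - (b * b + c * c) / (2 * a * a), 0.0))
    axis_sum = a + b + c
    if axis_sum <= DEGENERACY_TOL:
        dd = math.nan
        degenerate = True
    else:
        dd = 3.0 * float(np.linalg.norm(e.center)) / axis_sum
    return GPSEParams(V=v, E=ecc, D_dagger=dd, degenerate=degenerate)


def gpse_axis_orientation(e: Ellipsoid, tol: float = 1e-8):
    """Angles (rad, in [0, pi/2]) between the long axis and the S1/S2/S3
    coordinate axes.

    Returns ``{"S1": .., "S2": .., "S3": .., "defined": bool}``; when the
    long axis is not unique (``a ~ b``) the angles are NaN with
    ``defined = False``.
    """
    a, b, _ = e.semi_axes
    if a < DEGENERACY_TOL or a - b <= tol * max(a, 1.0):
        return {"S1": math.nan, "S2": math.nan, "S3": math.nan, "defined": False}
    long_axis = e.orientation[:, 0]
    ang = [math.acos(min(abs(float(long_axis[i])), 1.0)) for i in range(3)]
    return {"S1": ang[0], "S2": ang[1], "S3": ang[2], "defined": True}


def region_mean_mueller(img: MuellerImage, mask: np.ndarray) -> MuellerMatrix:
    """Element-wise mean Mueller matrix over a pixel mask, then normalized."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (img.height, img.width):
        raise ParameterError(
            f"mask shape {mask.shape} does not match image "
            f"{(img.height, img.width)}"
        )
    if not mask.any():
        raise ParameterError("mask selects no pixels")
    mean = img.m[mask].mean(axis=0)
    return normalize_mueller(MuellerMatrix(mean))


def gpse_from_mueller(
    m: MuellerMatrix, states: Optional[Sequence[StateSample]] = None,
    check_physical: bool = True,
):
    """Convenience pipeline: cloud -> ellipsoid -> parameters.

    Returns ``(cloud, ellipsoid, params)``."""
    if states is None:
        states = sample_full_polarization_states(2000)
    cloud = gpse_point_cloud(m, states, check_physical=check_physical)
    ell = fit_gpse_ellipsoid(cloud)
    return cloud, ell, gpse_parameters(ell)


def gpse_map(img: MuellerImage, states: Optional[Sequence[StateSample]] = None):
    """Per-pixel V / E / D-dagger maps of a Mueller image.

    Pixels are processed in scan order with no smoothing.  Returns a dict
    with float maps ``V``, ``E``, ``D_dagger`` and a boolean ``degenerate``
    mask; collapsed pixels carry NaN where the descriptor is undefined.
    """
    if states is None:
        states = sample_full_polarization_states(500)
    dirs = np.stack([s.direction for s in states])
    h, w = img.height, img.width
    out = {
        "V": np.full((h, w), np.nan),
        "E": np.full((h, w), np.nan),
        "D_dagger": np.full((h, w), np.nan),
        "degenerate": np.zeros((h, w), dtype=bool),
    }
    for r in range(h):
        for c in range(w):
            pts = _project_directions(img.m[r, c], dirs)
            ell = fit_gpse_ellipsoid(GPSEPointCloud(pts, states))
            par = gpse_parameters(ell)
            out["V"][r, c] = par.V
            out["E"][r, c] = par.E
            out["D_dagger"][r, c] = par.D_dagger
            out["degenerate"][r, c] = par.degenerate
    return out


def optimal_incident_state(
    m1: MuellerMatrix, m2: MuellerMatrix, states: Optional[Sequence[StateSample]] = None
):
    """Incident state maximizing the Poincare-space contrast between two
    media.

    The Euclidean distance between the two projected points of the same
    incident state is the polarization contrast obtainable by probing both
    media with that state; the argmax (first occurrence on ties, in the
    deterministic sampling order) is the optimal probe.  Returns
    ``(best_state, distance, distances)``.
    """
    if states is None:
        states = sample_full_polarization_states(2000)
    dirs = np.stack([s.direction for s in states])
    p1 = _project_directions(m1.m, dirs)
    p2 = _project_directions(m2.m, dirs)
    dist = np.linalg.norm(p1 - p2, axis=1)
    # first occurrence among near-ties (relative 1e-12) in sampling order
    best = dist.max()
    k = int(np.argmax(dist >= best - 1e-12 * max(best, 1.0)))
    return states[k], float(dist[k]), dist
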