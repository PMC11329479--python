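"""Stokes/Mueller primitives.

A beam of (possibly partially polarized) light is described by a Stokes
vector ``(S0, S1, S2, S3)``: total intensity, 0/90-degree linear preference,
45/135-degree linear preference and circular preference.  A linear medium
maps Stokes vectors through its 4x4 real Mueller matrix, ``S' = M . S``.
This module provides those two containers, a per-pixel Mueller image, the
basic operations (normalization, application, degree of polarization) and a
Cloude coherency-matrix physical-realizability check.

Conventions
-----------
* Matrix elements are referred to in the 1-based ``m11 .. m44`` notation in
  documentation and file formats; in-memory storage is a row-major ndarray.
* A *normalized* Mueller matrix has ``m11 = 1`` (all elements divided by the
  unpolarized transmittance).
* Retarder handedness follows Goldstein: a linear retarder with fast axis at
  0 deg and retardance ``delta`` maps ``S2 -> S2 cos(delta) - S3 sin(delta)``
  and ``S3 -> S2 sin(delta) + S3 cos(delta)`` ... see
  :func:`gpse.synth.retarder_mueller` for the explicit element pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidMatrixError, InvalidStateError

__all__ = [
    "DOP_TOL",
    "StokesVector",
    "PoincarePoint",
    "MuellerMatrix",
    "MuellerImage",
    "RealizabilityReport",
    "normalize_mueller",
    "apply_mueller",
    "degree_of_polarization",
    "physical_realizability",
]

#: absolute slack allowed above a degree of polarization of 1 before a state
#: is declared unphysical (values inside the band are clipped to 1).
DOP_TOL = 1e-9


@dataclass(frozen=True)
class StokesVector:
    """A 4-component Stokes vector ``(s0, s1, s2, s3)``.

    ``s0`` is the total intensity (arbitrary units, > 0 for physical
    states); ``s1, s2, s3`` carry the polarization content in the same
    units.
    """

    s0: float
    s1: float
    s2: float
    s3: float

    @classmethod
    def from_array(cls, a) -> "StokesVector":
        a = np.asarray(a, dtype=float).reshape(4)
        return cls(*a.tolist())

    def to_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @property
    def dop(self) -> float:
        return degree_of_polarization(self)


@dataclass(frozen=True)
class PoincarePoint:
    """A point in the Poincare ball (axes S1, S2, S3, dimensionless).

    The distance from the origin equals the degree of polarization of the
    state the point represents; the origin is completely unpolarized light
    and the unit sphere holds the fully polarized states.
    """

    p1: float
    p2: float
    p3: float

    def to_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3], dtype=float)

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.p1**2 + self.p2**2 + self.p3**2))


@dataclass
class MuellerMatrix:
    """A 4x4 real Mueller matrix.

    Parameters
    ----------
    m
        4x4 array of elements, row-major; ``m[0, 0]`` is the element written
        ``m11`` in the polarimetry literature.
    normalized
        True when ``m11 == 1``.  Set automatically by the constructor.
    """

    m: np.ndarray
    normalized: bool = field(default=False)

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (4, 4):
            raise InvalidMatrixError(
                f"Mueller matrix must be 4x4, got shape {self.m.shape}"
            )
        self.normalized = bool(abs(self.m[0, 0] - 1.0) < 1e-12)

    @classmethod
    def identity(cls) -> "MuellerMatrix":
        return cls(np.eye(4))

    @property
    def m11(self) -> float:
        return float(self.m[0, 0])

    def normalize(self) -> "MuellerMatrix":
        return normalize_mueller(self)

    def __matmul__(self, other):
        if isinstance(other, MuellerMatrix):
            return MuellerMatrix(self.m @ other.m)
        if isinstance(other, StokesVector):
            return apply_mueller(self, other)
        return NotImplemented


@dataclass
class MuellerImage:
    """A per-pixel Mueller matrix image, stored as an (H, W, 4, 4) array."""

    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 4 or self.m.shape[2:] != (4, 4):
            raise InvalidMatrixError(
                f"Mueller image must have shape (H, W, 4, 4), got {self.m.shape}"
            )

    @property
    def height(self) -> int:
        return self.m.shape[0]

    @property
    def width(self) -> int:
        return self.m.shape[1]

    def pixel(self, row: int, col: int) -> MuellerMatrix:
        return MuellerMatrix(self.m[row, col])

    @classmethod
    def from_planes(cls, planes: np.ndarray) -> "MuellerImage":
        """Build from 16 planes ordered m11, m12, ..., m44."""
        planes = np.asarray(planes, dtype=float)
        if planes.ndim != 3 or planes.shape[0] != 16:
            raise InvalidMatrixError(
                f"expected 16 planes of identical shape, got {planes.shape}"
            )
        h, w = planes.shape[1:]
        return cls(planes.reshape(4, 4, h, w).transpose(2, 3, 0, 1))

    def to_planes(self) -> np.ndarray:
        """Return the 16 planes ordered m11, m12, ..., m44."""
        h, w = self.height, self.width
        return self.m.transpose(2, 3, 0, 1).reshape(16, h, w)


def normalize_mueller(m: MuellerMatrix) -> MuellerMatrix:
    """Divide every element by m11 so the result has unit m11."""
    m11 = m.m[0, 0]
    if not m11 > 0:
        raise InvalidMatrixError(f"cannot normalize: m11 = {m11} is not positive")
    out = MuellerMatrix(m.m / m11)
    out.normalized = True
    return out


def apply_mueller(m: MuellerMatrix, s: StokesVector) -> StokesVector:
    """Apply the medium to a state: ``S' = M . S``."""
    return StokesVector.from_array(m.m @ s.to_array())


def degree_of_polarization(s: StokesVector) -> float:
    """``sqrt(s1^2 + s2^2 + s3^2) / s0``, clipped to 1 within ``DOP_TOL``."""
    if not s.s0 > 0:
        raise InvalidStateError(f"s0 = {s.s0} is not positive")
    dop = float(np.sqrt(s.s1**2 + s.s2**2 + s.s3**2) / s.s0)
    if dop > 1.0:
        if dop <= 1.0 + DOP_TOL:
            return 1.0
        raise InvalidStateError(f"degree of polarization {dop} exceeds 1")
    return dop


@dataclass(frozen=True)
class RealizabilityReport:
    is_physical: bool
    min_coherency_eigenvalue: float
    eigenvalues: np.ndarray


# Pauli spin basis used to build the Cloude coherency matrix.
_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)


def coherency_matrix(m: MuellerMatrix) -> np.ndarray:
    """Cloude coherency matrix ``H = 1/4 sum_ij m_ij (sigma_i x sigma_j*)``.

    H is Hermitian; the Mueller matrix is a physical (completely positive)
    map iff all four eigenvalues of H are non-negative.
    """
    h = np.zeros((4, 4), dtype=complex)
    for i in range(4):
        for j in range(4):
            h += m.m[i, j] * np.kron(_PAULI[i], _PAULI[j].conj())
    return h / 4.0


def physical_realizability(m: MuellerMatrix) -> RealizabilityReport:
    """Check complete positivity via the coherency-matrix eigenvalues.

    Physical iff the smallest eigenvalue is >= ``-1e-9 * m11`` (relative
    tolerance against the unpolarized transmittance).  Always returns a
    report, never raises.
    """
    h = coherency_matrix(m)
    eig = np.linalg.eigvalsh(h)
    tol = 1e-9 * abs(m.m[0, 0])
    return RealizabilityReport(
        is_physical=bool(eig.min() >= -tol),
        min_coherency_eigenvalue=float(eig.min()),
        eigenvalues=eig,
    )
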