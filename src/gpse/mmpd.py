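"""Mueller matrix polar decomposition (Lu-Chipman) and dual-wavelength
linear-retardance unwrapping.

A normalized Mueller matrix factors as ``M = M_depol . M_ret . M_diatt``: a
diattenuator (polarization-dependent transmittance), then a retarder (a
rigid rotation of the Poincare ball), then a depolarizer.  Scalar summary
parameters:

* diattenuation ``D = sqrt(m12^2 + m13^2 + m14^2)``
* total retardance ``R = arccos(tr(M_ret)/2 - 1)``
* depolarization ``Delta = 1 - |tr(M_depol) - 1| / 3``
* linear retardance
  ``delta = arccos( sqrt((r22 + r33)^2 + (r32 - r23)^2) - 1 )``
  (1-based element indices of the retarder factor).

The arccos folds the true linear retardance into [0, pi]: a medium whose
physical phase delay keeps growing (e.g. tissue birefringence rising during
dehydration) produces an oscillating measured ``delta``.  Measuring at two
wavelengths and searching the candidate branches ``2 pi m +/- delta_meas``
for the pair consistent with non-dispersive birefringence
(``delta * lambda`` constant) recovers the true value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MuellerMatrix, normalize_mueller
from .errors import AmbiguousUnwrapError, ParameterError

__all__ = [
    "MMPDResult",
    "UnwrapResult",
    "mmpd_decompose",
    "diattenuation",
    "retardance_total",
    "linear_retardance",
    "depolarization_index",
    "dual_wavelength_unwrap",
    "fold_retardance",
]


@dataclass
class MMPDResult:
    """Factors and scalar parameters of the polar decomposition."""

    m_depol: MuellerMatrix
    m_ret: MuellerMatrix
    m_diatt: MuellerMatrix
    D: float
    R: float
    delta: float
    Delta: float
    singular_diattenuator: bool = False


def _clipped_arccos(x: float, warn_tol: float = 1e-6) -> float:
    if abs(x) > 1.0 + warn_tol:
        warnings.warn(
            f"arccos argument {x} clipped to [-1, 1] beyond tolerance",
            stacklevel=3,
        )
    return math.acos(min(1.0, max(-1.0, x)))


def diattenuation(m: MuellerMatrix) -> float:
    """``D = sqrt(m12^2 + m13^2 + m14^2)`` of a normalized matrix."""
    mm = m.m if m.normalized else normalize_mueller(m).m
    return float(np.linalg.norm(mm[0, 1:]))


def retardance_total(m_ret: MuellerMatrix) -> float:
    """Total retardance ``R = arccos(tr(M_ret)/2 - 1)`` in [0, pi]."""
    return _clipped_arccos(float(np.trace(m_ret.m)) / 2.0 - 1.0)


def linear_retardance(m_ret: MuellerMatrix) -> float:
    """Linear retardance of a retarder factor, folded into [0, pi]."""
    r = m_ret.m
    return _clipped_arccos(
        math.hypot(r[1, 1] + r[2, 2], r[2, 1] - r[1, 2]) - 1.0
    )


def depolarization_index(m_depol: MuellerMatrix) -> float:
    """``Delta = 1 - |tr(M_depol) - 1| / 3`` in [0, 1]."""
    return 1.0 - abs(float(np.trace(m_depol.m)) - 1.0) / 3.0


def fold_retardance(delta_true: float) -> float:
    """Triangle-fold a non-negative retardance into [0, pi] (the arccos
    branch): ``fold(x) = |((x + pi) mod 2 pi) - pi|``."""
    return abs(math.remainder(delta_true, 2 * math.pi))


def mmpd_decompose(m: MuellerMatrix) -> MMPDResult:
    """Lu-Chipman polar decomposition ``M = M_depol . M_ret . M_diatt``.

    The diattenuator is built from the first row; the depolarizer's 3x3
    block is the symmetric square root of ``m' m'^T`` with its sign fixed
    by ``sign(det m')``; the retarder is the remaining proper rotation.
    A singular diattenuator (D -> 1) is inverted in the pseudoinverse
    limit and flagged.
    """
    if not m.normalized:
        m = normalize_mueller(m)
    mm = m.m
    dvec = mm[0, 1:].copy()
    d = float(np.linalg.norm(dvec))
    singular = d >= 1.0 - 1e-9
    d = min(d, 1.0)

    # diattenuator factor
    if d > 1e-15:
        dhat = dvec / np.linalg.norm(dvec)
        q = math.sqrt(max(1.0 - d * d, 0.0))
        md_small = q * np.eye(3) + (1.0 - q) * np.outer(dhat, dhat)
    else:
        md_small = np.eye(3)
    m_diatt = np.eye(4)
    m_diatt[0, 1:] = dvec
    m_diatt[1:, 0] = dvec
    m_diatt[1:, 1:] = md_small

    if singular:
        m_prime = mm @ np.linalg.pinv(m_diatt)
    else:
        m_prime = mm @ np.linalg.inv(m_diatt)

    p_delta = m_prime[1:, 0]
    mp = m_prime[1:, 1:]
    # left polar decomposition m' = (s U Sigma U^T)(s U V^T): depolarizer
    # block is the symmetric factor, retarder block the proper rotation
    u, sig, vt = np.linalg.svd(mp)
    det_mp = float(np.linalg.det(mp))
    if det_mp < 0:
        sign = -1.0
    else:
        sign = 1.0
    m_depol_small = sign * (u * sig) @ u.T
    w = u @ vt
    if np.linalg.det(w) * sign < 0:
        # fix handedness through the null direction (only possible when mp
        # is singular or det < 0)
        u2 = u.copy()
        u2[:, -1] = -u2[:, -1]
        w = u2 @ vt
    m_ret_small = sign * w

    m_depol = np.eye(4)
    m_depol[1:, 0] = p_delta
    m_depol[1:, 1:] = m_depol_small
    m_ret = np.eye(4)
    m_ret[1:, 1:] = m_ret_small

    m_ret_m = MuellerMatrix(m_ret)
    m_depol_m = MuellerMatrix(m_depol)
    return MMPDResult(
        m_depol=m_depol_m,
        m_ret=m_ret_m,
        m_diatt=MuellerMatrix(m_diatt),
        D=d,
        R=retardance_total(m_ret_m),
        delta=linear_retardance(m_ret_m),
        Delta=depolarization_index(m_depol_m),
        singular_diattenuator=singular,
    )


@dataclass(frozen=True)
class UnwrapResult:
    """Resolved true linear retardance at the first wavelength."""

    delta_true: float
    order: int
    branch: int
    residual: float


def dual_wavelength_unwrap(
    delta_meas_1: float,
    delta_meas_2: float,
    lambda_1: float,
    lambda_2: float,
    max_order: int = 3,
    threshold: float = 0.05,
) -> UnwrapResult:
    """Resolve phase wrapping by consistency across two wavelengths.

    Candidate true retardances at each wavelength are
    ``2 pi m + branch * delta_meas`` for ``m = 0..max_order`` and branch
    ``+/-1``.  Under non-dispersive birefringence the product
    ``delta * lambda`` is wavelength-independent; the candidate pair
    minimizing the mismatch (expressed in radians at ``lambda_1``) wins.
    Raises :class:`AmbiguousUnwrapError` when no pair is consistent within
    ``threshold`` radians.
    """
    for name, dm in (("delta_meas_1", delta_meas_1), ("delta_meas_2", delta_meas_2)):
        if not 0.0 <= dm <= math.pi + 1e-12:
            raise ParameterError(f"{name} = {dm} outside [0, pi]")
    if lambda_1 == lambda_2:
        raise ParameterError("wavelengths must differ")
    if max_order < 1:
        raise ParameterError("max_order must be >= 1")

    def candidates(dm):
        out = []
        for order in range(max_order + 1):
            for branch in (1, -1):
                val = 2 * math.pi * order + branch * dm
                if val >= -1e-12:
                    out.append((max(val, 0.0), order, branch))
        return out

    c1 = candidates(delta_meas_1)
    c2 = candidates(delta_meas_2)
    scored = []
    for v1, o1, b1 in c1:
        for v2, _, _ in c2:
            resid = abs(v1 * lambda_1 - v2 * lambda_2) / lambda_1
            scored.append((resid, v1, o1, b1))
    scored.sort(key=lambda t: t[0])
    best = scored[0]
    if best[0] > threshold:
        raise AmbiguousUnwrapError(
            f"no candidate pair consistent within {threshold} rad "
            f"(best residual {best[0]:.4g}); increase max_order?",
            candidates=scored[:5],
        )
    return UnwrapResult(
        delta_true=best[1], order=best[2], branch=best[3], residual=best[0]
    )
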