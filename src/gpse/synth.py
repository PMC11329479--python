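"""Synthetic tissue-like Mueller matrices.

Elementary polarization elements (retarder, diattenuator, depolarizer), a
fiber-ensemble tissue model, a dehydration time series and a two-region
phantom image.

The fiber-ensemble model emulates how anisotropic fibrous tissue (e.g.
skeletal muscle, connective tissue) shapes a Mueller matrix: each
realization is a linear retarder + diattenuator at a jittered fiber axis,
attenuated by an isotropic depolarizer, and the tissue matrix is the
ensemble average.  Retardance jitter stands in for birefringence disorder,
axis jitter for fiber orientation spread (FWHM = 2*sqrt(2 ln 2) * sigma),
diattenuation and the depolarization factor loosely proxy fiber content and
scattering.  It is an ensemble surrogate, not a photon-transport model:
it reproduces the qualitative parameter responses (eccentricity and center
displacement of the polarization ellipsoid grow with retardance magnitude,
fiber order and diattenuation) without simulating multiple scattering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MuellerImage, MuellerMatrix
from .errors import ParameterError

__all__ = [
    "FWHM_PER_SIGMA",
    "EnsembleTissueParams",
    "PhantomSpec",
    "retarder_mueller",
    "diattenuator_mueller",
    "depolarizer_mueller",
    "rotator_mueller",
    "ensemble_fibrous_mueller",
    "dehydration_series",
    "phantom_mueller_image",
    "random_physical_mueller",
]

#: conversion between full width at half maximum and standard deviation of a
#: Gaussian orientation distribution.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def retarder_mueller(delta: float, theta: float = 0.0) -> MuellerMatrix:
    """Linear retarder, retardance ``delta`` (rad), fast axis ``theta`` (rad).

    Goldstein convention: at ``theta = 0`` the (S2, S3) block is
    ``[[cos d, -sin d], [sin d, cos d]]`` acting from S3 row / S2 column, so
    a quarter-wave plate at 0 deg maps 45-deg linear light (0,0,1,0) to
    left-circular (0,0,0,-1).
    """
    c2, s2 = math.cos(2 * theta), math.sin(2 * theta)
    cd, sd = math.cos(delta), math.sin(delta)
    return MuellerMatrix(
        np.array(
            [
                [1, 0, 0, 0],
                [0, c2 * c2 + s2 * s2 * cd, s2 * c2 * (1 - cd), -s2 * sd],
                [0, s2 * c2 * (1 - cd), s2 * s2 + c2 * c2 * cd, c2 * sd],
                [0, s2 * sd, -c2 * sd, cd],
            ]
        )
    )


def diattenuator_mueller(d: float, theta: float = 0.0) -> MuellerMatrix:
    """Normalized linear diattenuator with diattenuation ``d`` at axis ``theta``.

    First row is ``(1, d cos 2theta, d sin 2theta, 0)``; the transverse
    block is scaled by ``sqrt(1 - d^2)``.  ``d = 1`` is an ideal polarizer.
    """
    if not 0.0 <= d <= 1.0:
        raise ParameterError(f"diattenuation d = {d} outside [0, 1]")
    c2, s2 = math.cos(2 * theta), math.sin(2 * theta)
    q = math.sqrt(1.0 - d * d)
    return MuellerMatrix(
        np.array(
            [
                [1, d * c2, d * s2, 0],
                [d * c2, c2 * c2 + s2 * s2 * q, c2 * s2 * (1 - q), 0],
                [d * s2, c2 * s2 * (1 - q), s2 * s2 + c2 * c2 * q, 0],
                [0, 0, 0, q],
            ]
        )
    )


def depolarizer_mueller(p1: float, p2: float, p3: float) -> MuellerMatrix:
    """Diagonal depolarizer ``diag(1, p1, p2, p3)``; ``(0,0,0)`` is ideal."""
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} = {p} outside [0, 1]")
    return MuellerMatrix(np.diag([1.0, p1, p2, p3]))


def rotator_mueller(phi: float) -> MuellerMatrix:
    """Optical rotator: rigid rotation by ``2*phi`` in the (S1, S2) plane."""
    c, s = math.cos(2 * phi), math.sin(2 * phi)
    return MuellerMatrix(
        np.array([[1, 0, 0, 0], [0, c, -s, 0], [0, s, c, 0], [0, 0, 0, 1]])
    )


@dataclass(frozen=True)
class EnsembleTissueParams:
    """Knobs of the fiber-ensemble tissue model.

    delta0, sigma_delta
        Mean and SD of the per-realization linear retardance (rad); the mean
        stands in for birefringence, the SD for retardance disorder.
    theta0, sigma_theta
        Mean and SD of the fiber axis (rad); sigma_theta is the orientation
        spread (FWHM = ``FWHM_PER_SIGMA * sigma_theta``); jitter beyond
        pi/2 from the mean is resampled (truncated normal).
    d
        Linear diattenuation along the per-realization axis, in [0, 1).
    p
        Isotropic depolarization factor in [0, 1] (1 = none).
    order
        Composition order per realization; only "DRT"
        (depolarizer . retarder . diattenuator) is the default; "TRD"
        reverses it.
    K
        Number of ensemble realizations for sampled mode.
    seed
        RNG seed for sampled mode.
    """

    delta0: float = 0.7
    sigma_delta: float = 0.3
    theta0: float = 0.0
    sigma_theta: float = 0.0
    d: float = 0.0
    p: float = 1.0
    order: str = "DRT"
    K: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.d < 1.0:
            raise ParameterError(f"d = {self.d} outside [0, 1)")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p = {self.p} outside [0, 1]")
        if self.sigma_delta < 0 or self.sigma_theta < 0:
            raise ParameterError("jitter SDs must be non-negative")
        if self.K < 1:
            raise ParameterError(f"K = {self.K} must be >= 1")
        if self.order not in ("DRT", "TRD"):
            raise ParameterError(f"unknown composition order {self.order!r}")


def _retarder_stack(delta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Vectorized retarder matrices, shape (K, 4, 4)."""
    c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    k = delta.shape[0]
    m = np.zeros((k, 4, 4))
    m[:, 0, 0] = 1
    m[:, 1, 1] = c2 * c2 + s2 * s2 * cd
    m[:, 1, 2] = s2 * c2 * (1 - cd)
    m[:, 1, 3] = -s2 * sd
    m[:, 2, 1] = m[:, 1, 2]
    m[:, 2, 2] = s2 * s2 + c2 * c2 * cd
    m[:, 2, 3] = c2 * sd
    m[:, 3, 1] = s2 * sd
    m[:, 3, 2] = -c2 * sd
    m[:, 3, 3] = cd
    return m


def _diattenuator_stack(d: float, theta: np.ndarray) -> np.ndarray:
    c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
    q = math.sqrt(1.0 - d * d)
    k = theta.shape[0]
    m = np.zeros((k, 4, 4))
    m[:, 0, 0] = 1
    m[:, 0, 1] = d * c2
    m[:, 0, 2] = d * s2
    m[:, 1, 0] = d * c2
    m[:, 1, 1] = c2 * c2 + s2 * s2 * q
    m[:, 1, 2] = c2 * s2 * (1 - q)
    m[:, 2, 0] = d * s2
    m[:, 2, 1] = m[:, 1, 2]
    m[:, 2, 2] = s2 * s2 + c2 * c2 * q
    m[:, 3, 3] = q
    return m


def _truncated_normal(rng, mean, sd, bound, size):
    """Normal(mean, sd) with |x - mean| <= bound, by resampling."""
    x = rng.normal(mean, sd, size)
    if sd > 0:
        bad = np.abs(x - mean) > bound
        while bad.any():
            x[bad] = rng.normal(mean, sd, bad.sum())
            bad = np.abs(x - mean) > bound
    return x


def ensemble_fibrous_mueller(
    params: EnsembleTissueParams, mode: str = "sampled"
) -> MuellerMatrix:
    """Ensemble-averaged Mueller matrix of a disordered fiber bundle.

    ``sampled`` draws ``K`` realizations
    ``Depolarizer(p) . Retarder(delta_k, theta_k) . Diattenuator(d, theta_k)``
    with ``delta_k ~ N(delta0, sigma_delta)`` and ``theta_k`` truncated
    normal, and averages them.  ``analytic`` (requires ``sigma_theta = 0``
    and ``d = 0``) uses the Gaussian characteristic function
    ``E[e^{i delta}] = e^{i delta0} e^{-sigma^2/2}``: the (S2, S3) rotation
    block of the mean retarder at axis theta0 shrinks by
    ``e^{-sigma_delta^2 / 2}`` while the axis direction is preserved.
    """
    if mode == "analytic":
        if params.sigma_theta != 0.0 or params.d != 0.0:
            raise ParameterError(
                "analytic mode requires sigma_theta = 0 and d = 0"
            )
        shrink = math.exp(-params.sigma_delta**2 / 2.0)
        cd, sd = math.cos(params.delta0), math.sin(params.delta0)
        # retarder elements are affine in (cos delta, sin delta); averaging
        # over Normal(delta0, sigma) scales both by e^{-sigma^2/2}
        c2, s2 = math.cos(2 * params.theta0), math.sin(2 * params.theta0)
        ecd, esd = shrink * cd, shrink * sd
        m = np.array(
            [
                [1, 0, 0, 0],
                [0, c2 * c2 + s2 * s2 * ecd, s2 * c2 * (1 - ecd), -s2 * esd],
                [0, s2 * c2 * (1 - ecd), s2 * s2 + c2 * c2 * ecd, c2 * esd],
                [0, s2 * esd, -c2 * esd, ecd],
            ]
        )
        m = depolarizer_mueller(params.p, params.p, params.p).m @ m
        return MuellerMatrix(m)
    if mode != "sampled":
        raise ParameterError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(params.seed)
    delta = rng.normal(params.delta0, params.sigma_delta, params.K)
    theta = _truncated_normal(
        rng, params.theta0, params.sigma_theta, math.pi / 2, params.K
    )
    ret = _retarder_stack(delta, theta)
    if params.d > 0:
        dia = _diattenuator_stack(params.d, theta)
        rt = np.einsum("kij,kjl->kil", ret, dia)
    else:
        rt = ret
    mean = rt.mean(axis=0)
    depol = depolarizer_mueller(params.p, params.p, params.p).m
    if params.order == "DRT":
        return MuellerMatrix(depol @ mean)
    return MuellerMatrix(mean @ depol)


def dehydration_series(
    n_steps: int = 19,
    delta0_path=(0.2, 3 * math.pi),
    jitter_coupling: float = 0.1,
    p_path=(0.6, 0.95),
    seed: int = 0,
    mode: str = "analytic",
):
    """Time series of tissue matrices with steadily growing retardance.

    Emulates slow tissue dehydration: the mean linear retardance ``delta0``
    ramps along ``delta0_path`` (tighter fiber packing -> higher effective
    birefringence) while the polarization-maintaining factor ``p`` ramps
    along ``p_path``; retardance jitter is coupled to the retardance,
    ``sigma_delta = jitter_coupling * delta0``, so disorder-linked
    depolarization grows with birefringence.

    Returns ``(matrices, ground_truth)`` where ``ground_truth`` is a dict of
    per-step arrays ``delta0``, ``sigma_delta``, ``p``.
    """
    delta0 = np.asarray(delta0_path, dtype=float)
    if delta0.size == 2 and n_steps != 2:
        delta0 = np.linspace(delta0[0], delta0[1], n_steps)
    p = np.asarray(p_path, dtype=float)
    if p.size == 2 and n_steps != 2:
        p = np.linspace(p[0], p[1], n_steps)
    if delta0.size != n_steps or p.size != n_steps:
        raise ParameterError("path lengths must match n_steps")
    sigma = jitter_coupling * delta0
    mats = []
    for i in range(n_steps):
        params = EnsembleTissueParams(
            delta0=float(delta0[i]),
            sigma_delta=float(sigma[i]),
            p=float(p[i]),
            seed=seed + i,
        )
        mats.append(ensemble_fibrous_mueller(params, mode=mode))
    truth = {"delta0": delta0, "sigma_delta": sigma, "p": p}
    return mats, truth


@dataclass
class PhantomSpec:
    """Two-region phantom: isotropic 'lobule-like' vs fibrous
    'connective-like' tissue, split left/right.

    ``noise`` is the SD of additive element noise on the raw matrix
    (0 = noise-free: every pixel of a region is that region's ensemble
    matrix).
    """

    height: int = 64
    width: int = 64
    isotropic: EnsembleTissueParams = field(
        default_factory=lambda: EnsembleTissueParams(
            delta0=0.0, sigma_delta=0.0, d=0.0, p=0.7
        )
    )
    fibrous: EnsembleTissueParams = field(
        default_factory=lambda: EnsembleTissueParams(
            delta0=0.7, sigma_delta=0.3, d=0.1, p=0.9
        )
    )
    noise: float = 0.0
    seed: int = 0


def phantom_mueller_image(spec: PhantomSpec):
    """Generate the two-region phantom.

    Returns ``(image, masks, truth)``: the MuellerImage, boolean masks
    ``{"isotropic": ..., "fibrous": ...}`` partitioning the image, and the
    per-region ground-truth ensemble matrices and parameters.
    """
    h, w = spec.height, spec.width
    masks = {
        "isotropic": np.zeros((h, w), dtype=bool),
        "fibrous": np.zeros((h, w), dtype=bool),
    }
    masks["isotropic"][:, : w // 2] = True
    masks["fibrous"][:, w // 2 :] = True

    m_iso = ensemble_fibrous_mueller(spec.isotropic, mode="sampled")
    m_fib = ensemble_fibrous_mueller(spec.fibrous, mode="sampled")
    img = np.empty((h, w, 4, 4))
    img[masks["isotropic"]] = m_iso.m
    img[masks["fibrous"]] = m_fib.m
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise, img.shape)
    truth = {
        "isotropic": {"matrix": m_iso, "params": spec.isotropic},
        "fibrous": {"matrix": m_fib, "params": spec.fibrous},
    }
    return MuellerImage(img), masks, truth


def random_physical_mueller(rng, depol_low: float = 0.1) -> MuellerMatrix:
    """Random physical matrix built as depolarizer . retarder . diattenuator.

    Convex-physical by construction (every factor is physical).  The
    depolarizer triple is rejection-sampled to satisfy the coherency
    conditions ``1 +/- p_i -/+ p_j - p_k >= 0`` (an anisotropic diagonal
    depolarizer is not automatically physical).  Useful for roundtrip and
    property tests.
    """
    while True:
        p = rng.uniform(depol_low, 1.0, size=3)
        p1, p2, p3 = p
        if (
            1 + p1 - p2 - p3 >= 0
            and 1 - p1 + p2 - p3 >= 0
            and 1 - p1 - p2 + p3 >= 0
        ):
            break
    delta = rng.uniform(0.0, 2 * math.pi)
    theta_r = rng.uniform(-math.pi / 2, math.pi / 2)
    d = rng.uniform(0.0, 0.9)
    theta_d = rng.uniform(-math.pi / 2, math.pi / 2)
    m = (
        depolarizer_mueller(*p).m
        @ retarder_mueller(delta, theta_r).m
        @ diattenuator_mueller(d, theta_d).m
    )
    return MuellerMatrix(m)
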