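"""Dual-rotating-retarder (DRR) Mueller polarimeter model.

The polarization state generator (PSG) is a fixed horizontal polarizer
followed by a quarter-wave plate rotating at rate ``w``; the analyzer (PSA)
mirrors it with its own quarter-wave plate rotating at ``5 w`` ahead of a
fixed horizontal polarizer.  Thirty intensity frames acquired while the
plates rotate encode all 16 Mueller elements; the detected intensity is a
truncated Fourier series in the generator angle,

    I(w) = alpha_0 + sum_{n=1..12} [alpha_n cos(2 n w) + beta_n sin(2 n w)],

whose 25 coefficients are linear in the Mueller elements.  Inversion is
done by direct least squares on the forward model; the Fourier-coefficient
route is provided as an equivalent view (both agree to rounding on
noise-free data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MuellerMatrix
from .errors import ConfigurationError, InvalidMatrixError
from .synth import retarder_mueller

__all__ = [
    "DRRConfig",
    "FourierSeries",
    "simulate_drr_intensities",
    "drr_fourier_coefficients",
    "reconstruct_mueller_from_drr",
]

N_HARMONICS = 12


@dataclass(frozen=True)
class DRRConfig:
    """Acquisition schedule and waveplate properties.

    ``psg_step`` degrees of generator-plate rotation per frame (the default
    6 deg over 30 frames spans the 180-deg fundamental period and exactly
    resolves harmonics up to ``2 * 12 w``); ``psa_ratio`` is the
    analyzer/generator rate ratio (5).  Retardances default to ideal
    quarter-wave plates.
    """

    n_frames: int = 30
    psg_step: float = 6.0
    psa_ratio: float = 5.0
    retardance_psg: float = math.pi / 2
    retardance_psa: float = math.pi / 2
    psg_start: float = 0.0
    psa_start: float = 0.0

    def __post_init__(self):
        if self.n_frames < 16:
            raise ConfigurationError(
                f"n_frames = {self.n_frames}: at least 16 frames are needed "
                "to determine 16 Mueller elements"
            )

    def angles(self):
        """(theta_psg, theta_psa) per frame, radians."""
        k = np.arange(self.n_frames)
        t1 = np.deg2rad(self.psg_start + k * self.psg_step)
        t2 = np.deg2rad(self.psa_start) + self.psa_ratio * np.deg2rad(
            k * self.psg_step
        )
        return t1, t2

    def generator_states(self) -> np.ndarray:
        """Stokes vectors leaving the PSG per frame, shape (n, 4)."""
        t1, _ = self.angles()
        s_pol = np.array([0.5, 0.5, 0.0, 0.0])  # unit input through polarizer
        return np.stack(
            [retarder_mueller(self.retardance_psg, t).m @ s_pol for t in t1]
        )

    def analyzer_rows(self) -> np.ndarray:
        """First row of the PSA chain per frame, shape (n, 4)."""
        _, t2 = self.angles()
        # horizontal polarizer first row is 0.5 * (1, 1, 0, 0)
        return np.stack(
            [
                0.5
                * (
                    retarder_mueller(self.retardance_psa, t).m[0]
                    + retarder_mueller(self.retardance_psa, t).m[1]
                )
                for t in t2
            ]
        )

    def design_matrix(self) -> np.ndarray:
        """(n_frames, 16) map from vec(M) (row-major) to intensities."""
        a = self.analyzer_rows()
        s = self.generator_states()
        return np.einsum("ki,kj->kij", a, s).reshape(self.n_frames, 16)


def simulate_drr_intensities(m: MuellerMatrix, cfg: DRRConfig = DRRConfig()):
    """Forward-model the 30 detected intensities for a sample ``m``."""
    intens = cfg.design_matrix() @ m.m.reshape(16)
    if intens.min() < -1e-12 * max(abs(m.m[0, 0]), 1.0):
        raise InvalidMatrixError(
            f"negative intensity {intens.min():.3g}: sample matrix is not "
            "physical for this measurement chain"
        )
    return np.clip(intens, 0.0, None)


@dataclass
class FourierSeries:
    """Coefficients of the ``2 n w`` intensity series, n = 0..12."""

    alpha: np.ndarray  # shape (13,): alpha_0 .. alpha_12
    beta: np.ndarray  # shape (12,): beta_1 .. beta_12

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        n = np.arange(1, N_HARMONICS + 1)
        arg = 2.0 * np.multiply.outer(w, n)
        return (
            self.alpha[0]
            + np.cos(arg) @ self.alpha[1:]
            + np.sin(arg) @ self.beta
        )


def _fourier_basis(w: np.ndarray) -> np.ndarray:
    n = np.arange(1, N_HARMONICS + 1)
    arg = 2.0 * np.multiply.outer(w, n)
    return np.column_stack([np.ones_like(w), np.cos(arg), np.sin(arg)])


def _check_fourier_identifiable(cfg: DRRConfig, basis: np.ndarray):
    if cfg.n_frames < 2 * N_HARMONICS + 1:
        raise ConfigurationError(
            f"{cfg.n_frames} frames cannot identify the "
            f"{2 * N_HARMONICS + 1} Fourier coefficients"
        )
    if np.linalg.cond(basis) > 1e8:
        raise ConfigurationError(
            "sampling schedule aliases the n <= 12 harmonics "
            "(ill-conditioned Fourier basis); refine psg_step"
        )


def drr_fourier_coefficients(intensities, cfg: DRRConfig = DRRConfig()) -> FourierSeries:
    """Project the intensity frames onto the ``2 n w`` Fourier basis."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape != (cfg.n_frames,):
        raise ConfigurationError(
            f"expected {cfg.n_frames} samples, got {intensities.shape}"
        )
    w, _ = cfg.angles()
    basis = _fourier_basis(w)
    _check_fourier_identifiable(cfg, basis)
    coef, *_ = np.linalg.lstsq(basis, intensities, rcond=None)
    return FourierSeries(alpha=coef[: N_HARMONICS + 1], beta=coef[N_HARMONICS + 1 :])


def reconstruct_mueller_from_drr(
    intensities, cfg: DRRConfig = DRRConfig(), method: str = "lstsq"
):
    """Invert measured frames to the raw (unnormalized) Mueller matrix.

    ``method="lstsq"`` solves the (n_frames x 16) forward system directly;
    ``method="fourier"`` first projects onto the Eq.-(1) coefficients and
    solves the coefficient-to-element linear map - the two agree to
    rounding on noise-free data.  Returns
    ``(MuellerMatrix, condition_number, residual)``.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 1:
        raise ConfigurationError("intensities must be a 1-D frame sequence")
    if intensities.shape[0] != cfg.n_frames:
        # allow reconstruction of truncated sequences via an adjusted config
        cfg = DRRConfig(
            n_frames=intensities.shape[0],
            psg_step=cfg.psg_step,
            psa_ratio=cfg.psa_ratio,
            retardance_psg=cfg.retardance_psg,
            retardance_psa=cfg.retardance_psa,
            psg_start=cfg.psg_start,
            psa_start=cfg.psa_start,
        )
    g = cfg.design_matrix()
    rank = np.linalg.matrix_rank(g)
    if rank < 16:
        raise ConfigurationError(
            f"measurement schedule is rank deficient: null space dimension "
            f"{16 - rank}"
        )
    if method == "lstsq":
        vec, *_ = np.linalg.lstsq(g, intensities, rcond=None)
    elif method == "fourier":
        w, _ = cfg.angles()
        basis = _fourier_basis(w)
        _check_fourier_identifiable(cfg, basis)
        coef, *_ = np.linalg.lstsq(basis, intensities, rcond=None)
        lmap, *_ = np.linalg.lstsq(basis, g, rcond=None)
        vec, *_ = np.linalg.lstsq(lmap, coef, rcond=None)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    m = MuellerMatrix(vec.reshape(4, 4))
    resid = float(np.linalg.norm(g @ vec - intensities))
    return m, float(np.linalg.cond(g)), resid
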