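"""Theoretical localization-precision estimators.

Two closed-form approximations to the Cramér-Rao lower bound for the
per-axis localization error of a 2D Gaussian spot on a pixelated detector
are provided, in the field's standard notation: *N* total signal
photoelectrons, *s* the PSF Gaussian standard deviation, *a* the pixel size
at the sample and *b²* the expected background photoelectrons per pixel.
The pixelation-corrected PSF width is sigma_a² = s² + a²/12.

Thompson et al.'s formula:

    <Δx²> = (s² + a²/12)/N + 8π s⁴ b² / (a² N²)

Mortensen et al.'s MLE formula:

    <Δx²> = (sigma_a²/N) · ( 1 + ∫₀¹ ln t / (1 + t/τ) dt )⁻¹,
    τ = 2π sigma_a² b² / (N a²)

The integral is negative and decreasing in τ, approaching −1 as
τ → ∞.  Note: the formula is sometimes transcribed with s²/N in the
prefactor; this module defaults to sigma_a²/N in both the prefactor and τ
(the original MLE derivation), controlled by ``use_sigma_a_prefactor``.
With b² = 0 the two estimators coincide exactly under that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PrecisionInputs",
    "thompson_precision",
    "mortensen_integral",
    "mortensen_precision",
    "pair_sigma_theo",
]


@dataclass
class PrecisionInputs:
    """Per-spot inputs to the precision formulas.

    ``bg_photons`` is b²: the expected background photoelectrons per pixel
    in the fitting window (equivalently the variance of the per-pixel
    background noise under Poisson statistics).  The fitted per-pixel
    background of a spot maps to it directly.
    """

    n_photons: float
    s_nm: float
    pixel_nm: float
    bg_photons: float = 0.0
    sigma_a_nm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise ValueError("n_photons must be > 0")
        if self.s_nm <= 0:
            raise ValueError("s_nm must be > 0")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.bg_photons < 0:
            raise ValueError("bg_photons must be >= 0")
        self.sigma_a_nm = math.sqrt(self.s_nm**2 + self.pixel_nm**2 / 12.0)


def thompson_precision(p: PrecisionInputs) -> float:
    """Per-axis localization std (nm), Thompson et al. formula."""
    var = (
        (p.s_nm**2 + p.pixel_nm**2 / 12.0) / p.n_photons
        + 8.0 * math.pi * p.s_nm**4 * p.bg_photons / (p.pixel_nm**2 * p.n_photons**2)
    )
    return math.sqrt(var)


def mortensen_integral(tau: float) -> float:
    """I(τ) = ∫₀¹ ln t / (1 + t/τ) dt, computed to ~1e-10 absolute.

    The substitution t = e^(−u) removes the integrable logarithmic
    singularity at t = 0:

        I(τ) = −∫₀^∞ u e^(−u) / (1 + e^(−u)/τ) du

    I(0) = 0; I is negative and strictly decreasing, with I(∞) = −1.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0.0:
        return 0.0

    def integrand(u: float) -> float:
        return -u * math.exp(-u) / (1.0 + math.exp(-u) / tau)

    val, _ = quad(integrand, 0.0, np.inf, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val


def mortensen_precision(p: PrecisionInputs, use_sigma_a_prefactor: bool = True) -> float:
    """Per-axis localization std (nm), Mortensen et al. MLE formula.

    Raises
    ------
    ValueError
        If the bracket 1 + I(τ) is not positive (background-dominated
        regime where the expansion diverges).
    """
    sa2 = p.sigma_a_nm**2
    tau = 2.0 * math.pi * sa2 * p.bg_photons / (p.n_photons * p.pixel_nm**2)
    bracket = 1.0 + mortensen_integral(tau)
    if bracket <= 0:
        raise ValueError(
            f"precision undefined in this regime: 1 + I(tau) = {bracket:.3g} <= 0"
        )
    prefactor = sa2 if use_sigma_a_prefactor else p.s_nm**2
    return math.sqrt(prefactor / p.n_photons / bracket)


def pair_sigma_theo(sigma1_nm: float, sigma2_nm: float) -> float:
    """Propagate two per-bead precisions to a pair-distance precision.

    The distance error is the quadrature sum sqrt(σ1² + σ2²): for beads
    separated by much more than σ, each bead's isotropic 2D error projects
    onto the separation axis with its per-axis std.
    """
    if sigma1_nm < 0 or sigma2_nm < 0:
        raise ValueError("precisions must be >= 0")
    return math.hypot(sigma1_nm, sigma2_nm)
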