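"""Overdamped (Drude-Lorentz) bath models and their exponential decompositions.

Each site of the aggregate couples to an independent thermal environment
characterized by a Drude-Lorentz spectral density

    J(omega) = 2 lambda gamma omega / (omega^2 + gamma^2)

with reorganization energy ``lambda`` and relaxation rate ``gamma`` (both
cm^-1).  At high temperature (gamma / k_B T < 1) the two-time bath
correlation function is a single decaying exponential for t >= 0,

    alpha(t) = g exp(-gamma t / hbar),    g = 2 lambda k_B T - i lambda gamma,

extended to negative times by the symmetry alpha(-t) = alpha(t)*.  Because
Im[alpha] flips sign at t = 0 this "naive" correlation function is
discontinuous there, which injects unphysical high-frequency content into
the stochastic driving noise.  The discontinuity is removed by splitting the
positive-time correlation into two continuous exponentials

    alpha(t) = alpha_0(t) + alpha_mark(t)
    alpha_0(t)    = g exp(-gamma |t| / hbar)
    alpha_mark(t) = -i Im[g] exp(-gamma_mark |t| / hbar)

where the fast "Markovian" mode (rate gamma_mark >> gamma) cancels the
imaginary part of the total correlation exactly at t = 0 and decays on the
timescale hbar/gamma_mark, after which the naive form is recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import HBAR, KB

__all__ = [
    "DrudeLorentzBath",
    "ExponentialMode",
    "spectral_density",
    "decompose_correlation",
    "correlation_function",
    "naive_correlation",
]


@dataclass(frozen=True)
class DrudeLorentzBath:
    """Per-site overdamped bath parameters.

    Parameters
    ----------
    lambda_reorg : float
        Reorganization energy lambda (cm^-1).
    gamma : float
        Bath relaxation rate gamma (cm^-1).
    temperature : float
        Temperature (K).
    gamma_mark : float or None
        Decay rate of the fast Markovian correction mode (cm^-1).  ``None``
        disables the correction (the naive discontinuous correlation is then
        used as-is, e.g. for single-mode reference calculations).
    """

    lambda_reorg: float
    gamma: float
    temperature: float
    gamma_mark: float | None = 500.0

    def __post_init__(self) -> None:
        if self.lambda_reorg <= 0:
            raise ValueError("lambda_reorg must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.gamma_mark is not None and self.gamma_mark <= self.gamma:
            raise ValueError("gamma_mark must exceed gamma")
        if self.gamma / (KB * self.temperature) >= 1.0:
            warnings.warn(
                "gamma/(k_B T) >= 1: the single-exponential high-temperature "
                "decomposition of the Drude-Lorentz correlation function is "
                "not reliable for this bath",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ExponentialMode:
    """One exponential term g exp(-gamma |t|/hbar) of a bath correlation.

    ``site`` tags which aggregate site the mode's environment belongs to;
    ``markovian`` marks the fast short-time-correction mode, which is kept
    only to first order in the hierarchy.
    """

    g: complex
    gamma: complex
    site: int
    markovian: bool = False

    def __post_init__(self) -> None:
        if np.real(self.gamma) <= 0:
            raise ValueError("every mode must decay: Re(gamma) > 0")


def spectral_density(bath: DrudeLorentzBath, omega):
    """Drude-Lorentz spectral density 2 lambda gamma omega/(omega^2+gamma^2).

    Antisymmetric in ``omega``; accepts scalars or arrays (cm^-1).
    """
    omega = np.asarray(omega, dtype=float)
    lam, gam = bath.lambda_reorg, bath.gamma
    out = 2.0 * lam * gam * omega / (omega**2 + gam**2)
    return out if out.ndim else float(out)


def decompose_correlation(bath: DrudeLorentzBath, site: int = 0) -> list[ExponentialMode]:
    """Exponential decomposition of a bath's correlation function.

    Returns ``[mode0]`` or ``[mode0, mark_mode]``: the slow mode carries
    g = 2 lambda k_B T - i lambda gamma at rate gamma; the Markovian mode
    carries g_mark = -i Im[g] = +i lambda gamma at rate gamma_mark, chosen so
    Im[alpha_0(0) + alpha_mark(0)] = 0.
    """
    lam, gam, T = bath.lambda_reorg, bath.gamma, bath.temperature
    g0 = complex(2.0 * lam * KB * T, -lam * gam)
    modes = [ExponentialMode(g=g0, gamma=complex(gam), site=site, markovian=False)]
    if bath.gamma_mark is not None:
        g_mark = complex(0.0, -g0.imag)
        modes.append(
            ExponentialMode(
                g=g_mark, gamma=complex(bath.gamma_mark), site=site, markovian=True
            )
        )
    return modes


def correlation_function(modes, t):
    """Total correlation alpha(t) = sum_i g_i exp(-gamma_i |t|/hbar).

    For t < 0 the Hermitian symmetry alpha(-t) = alpha(t)* is applied.
    Accepts scalar or array ``t`` (fs).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=complex)
    at = np.abs(t)
    for m in modes:
        out += m.g * np.exp(-m.gamma * at / HBAR)
    out = np.where(t >= 0, out, np.conj(out))
    return out if out.ndim else complex(out)


def naive_correlation(bath: DrudeLorentzBath, t):
    """Discontinuous Drude-Lorentz correlation (Re[g] + i sgn(t) Im[g]) e^{-gamma|t|/hbar}."""
    t = np.asarray(t, dtype=float)
    lam, gam, T = bath.lambda_reorg, bath.gamma, bath.temperature
    g = complex(2.0 * lam * KB * T, -lam * gam)
    sgn = np.where(t >= 0, 1.0, -1.0)
    out = (g.real + 1j * sgn * g.imag) * np.exp(-gam * np.abs(t) / HBAR)
    return out if out.ndim else complex(out)
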