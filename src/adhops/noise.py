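"""Colored complex Gaussian noise with prescribed bath correlation.

Each site is driven by an independent stationary circularly-symmetric
complex Gaussian process z_{n,t} with

    E[z_{n,t}] = 0,   E[z_{n,t} z_{n,s}] = 0,
    E[z_{n,t} z*_{n,s}] = alpha_n(t - s),

where alpha_n is the site's (decomposed) bath correlation function.  The
process is realized by spectral filtering on a circulant embedding: the
Hermitian extension of alpha is sampled on a ring of length >= 2x the
requested grid, Fourier transformed to a (real, non-negative) spectrum, and
white complex Gaussian noise is filtered through its square root.  Because
the white noise is circularly symmetric, the pseudo-correlation E[z z]
vanishes identically.

Per-site random streams are derived from the master seed with
``numpy.random.SeedSequence(seed, spawn_key=(site,))`` so that adding sites
to an aggregate never perturbs the noise of existing sites.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .bath import ExponentialMode, correlation_function
from .constants import HBAR

__all__ = ["NoiseTrajectory", "generate_noise", "noise_at"]

_SPECTRUM_TOL = 1e-8  # warn when spectra dip below this (relative)
_SPECTRUM_CLIP = 0.02  # error when spectra dip below this (relative)


@dataclass
class NoiseTrajectory:
    """Discretized per-site complex noise on a uniform time grid.

    ``z`` has shape (n_sites, n_t); values between grid points are defined
    by linear interpolation (see :func:`noise_at`).
    """

    t_axis: np.ndarray
    z: np.ndarray
    seed: int

    @property
    def dt(self) -> float:
        return float(self.t_axis[1] - self.t_axis[0]) if len(self.t_axis) > 1 else 0.0


def _site_modes(modes: list[ExponentialMode], n_sites: int):
    per_site: list[list[ExponentialMode]] = [[] for _ in range(n_sites)]
    for m in modes:
        per_site[m.site].append(m)
    return per_site


def generate_noise(
    modes: list[ExponentialMode],
    t_axis: np.ndarray,
    seed: int,
    n_sites: int | None = None,
) -> NoiseTrajectory:
    """Generate per-site noise whose correlation matches the summed modes.

    ``t_axis`` must be uniform starting at 0.  Raises ``ValueError`` if the
    circulant embedding of a site's correlation has a significantly negative
    spectrum (naming the worst offending mode).
    """
    t_axis = np.asarray(t_axis, dtype=float)
    if len(t_axis) > 1:
        steps = np.diff(t_axis)
        if not np.allclose(steps, steps[0], rtol=1e-10, atol=1e-12):
            raise ValueError("t_axis must be uniform")
        dt = steps[0]
    else:
        dt = 1.0
    n_t = len(t_axis)
    if n_sites is None:
        n_sites = max(m.site for m in modes) + 1
    # ring length: at least twice the grid, rounded to a power of two for FFT,
    # and long enough that the correlation has decayed at the ring midpoint
    # (the Hermitian circulant needs a real midpoint sample)
    decay = min(float(np.real(m.gamma)) for m in modes)
    t_decay = 25.0 * HBAR / decay if decay > 0 else 0.0
    L = 1
    while L < 2 * n_t or (L // 2) * dt < t_decay:
        L *= 2
        if L > 2**26:
            break

    per_site = _site_modes(modes, n_sites)
    z = np.zeros((n_sites, n_t), dtype=complex)
    half = L // 2
    t_ring = np.arange(half + 1) * dt
    for site in range(n_sites):
        site_modes = per_site[site]
        if not site_modes:
            continue
        alpha_pos = correlation_function(site_modes, t_ring)
        c = np.zeros(L, dtype=complex)
        c[: half + 1] = alpha_pos
        # Hermitian ring needs real lag-0 and midpoint samples: the lag-0
        # imaginary part is the symmetric midpoint of the sgn(t) jump (zero
        # for a decomposed pair), the ring midpoint has decayed
        c[0] = alpha_pos[0].real
        c[half] = alpha_pos[half].real
        c[half + 1 :] = np.conj(alpha_pos[1:half][::-1])
        spectrum = np.fft.fft(c)
        if np.max(np.abs(spectrum.imag)) > 1e-6 * max(np.max(np.abs(spectrum.real)), 1.0):
            raise ValueError("circulant spectrum unexpectedly non-Hermitian")
        S = spectrum.real
        smin, smax = S.min(), S.max()
        if smin < -_SPECTRUM_CLIP * smax:
            worst = _worst_mode(site_modes, dt, L)
            raise ValueError(
                f"non-positive-definite circulant embedding for site {site}: "
                f"min spectrum {smin:.3e}; worst offending mode {worst!r}"
            )
        if smin < -_SPECTRUM_TOL * smax:
            # discontinuous (uncorrected) correlations embed only
            # approximately; small negative spectral weight is dropped
            warnings.warn(
                f"clipping slightly negative circulant spectrum for site "
                f"{site} ({smin / smax:.2e} of maximum)",
                stacklevel=2,
            )
        S = np.clip(S, 0.0, None)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(site,)))
        w = (rng.standard_normal(L) + 1j * rng.standard_normal(L)) / np.sqrt(2.0)
        ring = np.fft.ifft(np.sqrt(S) * w) * np.sqrt(L)
        z[site] = ring[:n_t]
    return NoiseTrajectory(t_axis=t_axis, z=z, seed=seed)


def _worst_mode(site_modes, dt, L):
    """Mode whose individual circulant spectrum dips lowest (diagnostics)."""
    worst, worst_min = None, np.inf
    half = L // 2
    t_ring = np.arange(half + 1) * dt
    for m in site_modes:
        a = correlation_function([m], t_ring)
        c = np.zeros(L, dtype=complex)
        c[: half + 1] = a
        c[half + 1 :] = np.conj(a[1:half][::-1])
        smin = np.fft.fft(c).real.min()
        if smin < worst_min:
            worst, worst_min = m, smin
    return worst


def noise_at(traj: NoiseTrajectory, site: int, t: float) -> complex:
    """Noise value at arbitrary time by linear interpolation on the grid."""
    t_axis = traj.t_axis
    if t < t_axis[0] - 1e-9 or t > t_axis[-1] + 1e-9:
        raise ValueError(f"t={t} outside noise grid [{t_axis[0]}, {t_axis[-1]}]")
    t = min(max(t, t_axis[0]), t_axis[-1])
    dt = traj.dt
    if dt == 0.0:
        return complex(traj.z[site, 0])
    x = (t - t_axis[0]) / dt
    i = min(int(np.floor(x)), len(t_axis) - 2)
    frac = x - i
    return complex((1.0 - frac) * traj.z[site, i] + frac * traj.z[site, i + 1])


def noise_at_all(traj: NoiseTrajectory, t: float) -> np.ndarray:
    """Vector of all sites' noise at time ``t`` (linear interpolation)."""
    t_axis = traj.t_axis
    if t < t_axis[0] - 1e-9 or t > t_axis[-1] + 1e-9:
        raise ValueError(f"t={t} outside noise grid [{t_axis[0]}, {t_axis[-1]}]")
    t = min(max(t, t_axis[0]), t_axis[-1])
    dt = traj.dt
    if dt == 0.0:
        return traj.z[:, 0].copy()
    x = (t - t_axis[0]) / dt
    i = min(int(np.floor(x)), len(t_axis) - 2)
    frac = x - i
    return (1.0 - frac) * traj.z[:, i] + frac * traj.z[:, i + 1]
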