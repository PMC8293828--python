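"""Programmatic test systems and independent analytic/numeric oracles.

Everything the test surface needs is built here at run time: uniform linear
chains, the closed-form pure-dephasing (independent boson) coherence decay,
a dense deterministic integrator of the hierarchically-coupled
density-matrix equations (HEOM) sharing only the bath decomposition with the
stochastic code, and the Lindblad (Markovian) limit.  The HEOM and Lindblad
integrators never touch the stochastic equation-of-motion code, so they act
as equation-level cross-checks of the trajectory ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .bath import DrudeLorentzBath, ExponentialMode
from .constants import HBAR
from .eom import ModeSet
from .hierarchy import triangular_basis
from .system import SystemModel

__all__ = [
    "ChainSpec",
    "build_chain",
    "dephasing_oracle",
    "heom_oracle",
    "lindblad_oracle",
]

_SPARSE_THRESHOLD = 64
_HEOM_SITE_CAP = 3


@dataclass(frozen=True)
class ChainSpec:
    """Uniform linear chain: nearest-neighbor coupling, equal site energies."""

    n_sites: int
    coupling: float = 50.0
    site_energy: float = 0.0
    l_0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def build_chain(spec: ChainSpec) -> SystemModel:
    """Tridiagonal Frenkel Hamiltonian; sparse above a size threshold."""
    n, v, e = spec.n_sites, spec.coupling, spec.site_energy
    if n > _SPARSE_THRESHOLD:
        diags = [np.full(n, e), np.full(n - 1, v), np.full(n - 1, v)]
        h = sp.diags(diags, [0, 1, -1], format="csr", dtype=complex)
    else:
        h = np.diag(np.full(n, e, dtype=complex))
        if n > 1:
            h += np.diag(np.full(n - 1, v, dtype=complex), 1)
            h += np.diag(np.full(n - 1, v, dtype=complex), -1)
    return SystemModel(h)


def dephasing_oracle(modes: list[ExponentialMode], t_axis: np.ndarray) -> np.ndarray:
    """Closed-form independent-boson coherence decay for exponential baths.

    exp(-(1/hbar^2) int_0^t ds int_0^s ds' alpha(s')) with
    alpha(t) = sum_j g_j exp(-gamma_j t/hbar), evaluated analytically.
    """
    t = np.asarray(t_axis, dtype=float)
    K = np.zeros(len(t), dtype=complex)
    for m in modes:
        g, gam = m.g, m.gamma
        K += (g / (gam * HBAR)) * (t - (HBAR / gam) * (1.0 - np.exp(-gam * t / HBAR)))
    return np.exp(-K)


def _dense_h(system: SystemModel) -> np.ndarray:
    h = system.hamiltonian
    return np.asarray(h.todense()) if sp.issparse(h) else np.asarray(h)


def heom_oracle(
    system: SystemModel,
    baths: list[DrudeLorentzBath],
    k_max: int,
    t_axis: np.ndarray,
    rho0: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Dense deterministic hierarchical density-matrix dynamics.

    Uses the same exponential decomposition and truncation bookkeeping as
    the stochastic hierarchy (triangular bound over non-Markovian modes,
    first-order Markovian attachment) with auxiliaries scaled so both
    hierarchy couplings carry one power of 1/hbar:

        d rho^(k)/dt = -(i/hbar)[H, rho^(k)] - (k.gamma/hbar) rho^(k)
                       - (i/hbar) sum_n [L_n, rho^(k+e_n)]
                       - (i/hbar) sum_n k_n (g_n L_n rho^(k-e_n)
                                             - g_n* rho^(k-e_n) L_n)

    Returns rho(t) with shape (n_t, n, n).  Small systems only.
    """
    n = system.n_sites
    if n > _HEOM_SITE_CAP:
        raise ValueError(f"heom_oracle is capped at {_HEOM_SITE_CAP} sites")
    modeset = ModeSet.from_baths(baths)
    basis = triangular_basis(modeset.n_modes, k_max, modeset.markovian)
    n_aux = len(basis)
    h = _dense_h(system)
    pos = basis.position
    gvec, gamvec, sitevec = modeset.g, modeset.gamma, modeset.site

    depth_gamma = np.array(
        [sum(k * gamvec[m] for m, k in aux.pairs) for aux in basis.members]
    )
    links = []  # (row, mode, up_pos, down_pos, k_n)
    for i, aux in enumerate(basis.members):
        for m in range(modeset.n_modes):
            up = pos.get(aux.plus(m))
            dn_idx = aux.minus(m)
            dn = pos.get(dn_idx) if dn_idx is not None else None
            if up is not None or dn is not None:
                links.append((i, m, up, dn, aux.get(m)))

    if rho0 is None:
        rho0 = np.zeros((n, n), dtype=complex)
        rho0[n // 2, n // 2] = 1.0

    def rhs(_t, y):
        r = y.view(complex).reshape(n_aux, n, n)
        dr = np.empty_like(r)
        for i in range(n_aux):
            dr[i] = (-1j / HBAR) * (h @ r[i] - r[i] @ h) - (depth_gamma[i] / HBAR) * r[i]
        for i, m, up, dn, kn in links:
            s = int(sitevec[m])
            if up is not None:
                # [L_s, rho^(k+e)]
                dr[i, s, :] -= (1j / HBAR) * r[up, s, :]
                dr[i, :, s] += (1j / HBAR) * r[up, :, s]
            if dn is not None:
                c = 1j * kn / HBAR
                dr[i, s, :] -= c * gvec[m] * r[dn, s, :]
                dr[i, :, s] += c * np.conj(gvec[m]) * r[dn, :, s]
        return dr.ravel().view(float)

    y0 = np.zeros((n_aux, n, n), dtype=complex)
    y0[0] = rho0
    sol = solve_ivp(
        rhs,
        (float(t_axis[0]), float(t_axis[-1])),
        y0.ravel().view(float),
        t_eval=np.asarray(t_axis, dtype=float),
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"HEOM oracle integration failed: {sol.message}")
    out = sol.y.T.copy().view(complex).reshape(len(t_axis), n_aux, n, n)
    return out[:, 0]


def lindblad_oracle(
    system: SystemModel,
    baths: list[DrudeLorentzBath],
    t_axis: np.ndarray,
    rho0: np.ndarray | None = None,
) -> np.ndarray:
    """Markovian (fast-bath) limit of the dynamics.

    Each site dephases at rate 2 Re[w_n] with w_n = sum_j g_j/(gamma_j hbar)
    over the site's modes, and its energy is shifted by hbar Im[w_n] (the
    reorganization/Lamb shift surviving the Markov limit):

        d rho/dt = -(i/hbar)[H + sum_n hbar Im[w_n] L_n, rho]
                   + sum_n Re[w_n] (2 L_n rho L_n - {L_n, rho})
    """
    n = system.n_sites
    modeset = ModeSet.from_baths(baths)
    h = _dense_h(system).astype(complex).copy()
    w = np.zeros(n, dtype=complex)
    for j in range(modeset.n_modes):
        w[int(modeset.site[j])] += modeset.g[j] / (modeset.gamma[j] * HBAR)
    h[np.diag_indices(n)] += HBAR * w.imag
    rates = w.real

    if rho0 is None:
        rho0 = np.zeros((n, n), dtype=complex)
        rho0[n // 2, n // 2] = 1.0

    def rhs(_t, y):
        r = y.view(complex).reshape(n, n)
        dr = (-1j / HBAR) * (h @ r - r @ h)
        for s in range(n):
            g = rates[s]
            dr[s, s] += 2.0 * g * r[s, s]
            dr[s, :] -= g * r[s, :]
            dr[:, s] -= g * r[:, s]
        return dr.ravel().view(float)

    sol = solve_ivp(
        rhs,
        (float(t_axis[0]), float(t_axis[-1])),
        rho0.astype(complex).ravel().view(float),
        t_eval=np.asarray(t_axis, dtype=float),
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"Lindblad oracle integration failed: {sol.message}")
    return sol.y.T.copy().view(complex).reshape(len(t_axis), n, n)
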