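"""Equations of motion for the hierarchy of pure states (HOPS).

Three variants of the coupled auxiliary-wave-function equations are
implemented on top of one table-driven derivative engine:

``linear``
    d/dt psi^(k) = (-i H/hbar - (k.gamma)/hbar) psi^(k)
                   + sum_s L_s (z*_s/hbar) psi^(k)
                   + sum_n k_n (g_n/hbar) L_n psi^(k - e_n)
                   - sum_n (1/hbar) L_n^dag psi^(k + e_n)

    The stochastic wave functions are unnormalized; the reduced density
    matrix is the (norm-weighted) ensemble average of outer products.

``nonlinear``
    Same flux structure, with the effective noise z~*_s = z*_s + sum_n xi_n
    shifted by per-mode memory accumulators

        d xi_n/dt = (-gamma_n* xi_n + g_n* <L_n^dag>_t)/hbar,

    and the up-flux operator replaced by (L_n^dag - <L_n^dag>_t), where the
    expectation is taken in the normalized physical slice.  This is the
    norm-convergent form obtained from the linear equation by a Girsanov
    transformation; its ensemble average equals the linear one.

``normalized``
    The nonlinear equation after (i) rescaling auxiliary k by the product of
    (gamma_n/g_n)^{k_n} so that auxiliary magnitudes stay O(1) at every
    hierarchy depth (down-flux becomes k_n gamma_n/hbar, up-flux
    g_n/(gamma_n hbar)), and (ii) subtracting a scalar correction Gamma_t
    chosen so the physical-slice norm has exactly zero time derivative.

Units: energies cm^-1, time fs; the noise satisfies
E[z_t z*_s] = alpha(t - s) and enters the equations as z*/hbar.

System-bath coupling operators are site projectors L_n = |n><n| throughout,
which is what makes the flux terms local: amplitude only flows toward an
auxiliary through mode n when the source wave function has amplitude on
site n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bath import DrudeLorentzBath, ExponentialMode, decompose_correlation
from .constants import HBAR
from .hierarchy import AuxIndex, HierarchyBasis
from .system import SystemModel

__all__ = [
    "ModeSet",
    "HopsState",
    "DerivativeEngine",
    "linear_derivative",
    "nonlinear_derivative",
    "normalized_derivative",
    "apply_terminator",
]


class ModeSet:
    """All exponential bath modes of an aggregate, in fixed global order."""

    def __init__(self, modes: list[ExponentialMode]):
        self.modes = list(modes)
        self.g = np.array([m.g for m in modes], dtype=complex)
        self.gamma = np.array([m.gamma for m in modes], dtype=complex)
        self.site = np.array([m.site for m in modes], dtype=np.int64)
        self.markovian = np.array([m.markovian for m in modes], dtype=bool)
        self.n_modes = len(modes)

    @classmethod
    def from_baths(cls, baths: list[DrudeLorentzBath]) -> "ModeSet":
        modes: list[ExponentialMode] = []
        for site, bath in enumerate(baths):
            if bath is not None:
                modes.extend(decompose_correlation(bath, site=site))
        return cls(modes)

    def modes_of_sites(self, sites) -> np.ndarray:
        """Global mode indices whose environment lives on one of ``sites``."""
        mask = np.isin(self.site, sites)
        return np.nonzero(mask)[0]


@dataclass
class HopsState:
    """Wave functions over the current basis plus per-mode noise memory.

    ``wavefunctions`` has shape (n_aux, n_state): rows follow
    ``basis.members`` order, columns follow the sorted global site indices
    in ``state_sites``.  ``memory`` holds xi_n for every global mode.
    """

    wavefunctions: np.ndarray
    memory: np.ndarray
    time: float
    basis: HierarchyBasis
    state_sites: np.ndarray = field(default=None)

    @property
    def physical(self) -> np.ndarray:
        return self.wavefunctions[0]

    def physical_norm(self) -> float:
        return float(np.linalg.norm(self.wavefunctions[0]))


class DerivativeEngine:
    """Precomputed connectivity tables for fast derivative evaluation on a
    fixed (possibly adaptive) auxiliary/state basis.

    Cost of one evaluation is proportional to (basis size) x (active modes),
    independent of the total aggregate size.
    """

    def __init__(
        self,
        system: SystemModel,
        modeset: ModeSet,
        basis: HierarchyBasis,
        state_sites: np.ndarray | None = None,
        variant: str = "normalized",
        k_max: int | None = None,
        terminator: bool = False,
    ):
        if variant not in ("linear", "nonlinear", "normalized"):
            raise ValueError(f"unknown variant {variant!r}")
        self.system = system
        self.modeset = modeset
        self.basis = basis
        self.variant = variant
        self.terminator = terminator
        self.k_max = k_max
        if state_sites is None:
            state_sites = np.arange(system.n_sites)
        self.state_sites = np.asarray(sorted(state_sites), dtype=np.int64)
        self.n_state = len(self.state_sites)
        self.n_aux = len(basis)
        self.site_to_col = {int(s): i for i, s in enumerate(self.state_sites)}
        self.h_sub = system.sub_hamiltonian(self.state_sites)

        markset = frozenset(np.nonzero(modeset.markovian)[0].tolist())
        # per-auxiliary total damping  sum_n k_n gamma_n  and non-Markovian depth
        depth_gamma = np.zeros(self.n_aux, dtype=complex)
        depth_nm = np.zeros(self.n_aux, dtype=np.int64)
        has_mark = np.zeros(self.n_aux, dtype=bool)
        for i, aux in enumerate(basis.members):
            for m, k in aux.pairs:
                depth_gamma[i] += k * modeset.gamma[m]
                if m in markset:
                    has_mark[i] = True
                else:
                    depth_nm[i] += k
        self.depth_gamma = depth_gamma

        active = modeset.modes_of_sites(self.state_sites)
        self.active_modes = active
        # connectivity tables per active mode
        self.tables = []
        pos = basis.position
        for n in active:
            n = int(n)
            col = self.site_to_col[int(modeset.site[n])]
            dn_rows, dn_pos, dn_k = [], [], []
            up_rows, up_pos = [], []
            term_rows, term_k = [], []
            is_mark = bool(modeset.markovian[n])
            for i, aux in enumerate(basis.members):
                kn = aux.get(n)
                if kn:
                    down = aux.minus(n)
                    j = pos.get(down)
                    if j is not None:
                        dn_rows.append(i)
                        dn_pos.append(j)
                        dn_k.append(kn)
                up = aux.plus(n)
                j = pos.get(up)
                if j is not None:
                    up_rows.append(i)
                    up_pos.append(j)
                elif (
                    terminator
                    and not is_mark
                    and k_max is not None
                    and not has_mark[i]
                    and depth_nm[i] >= k_max
                ):
                    # up-neighbor truncated by the depth bound: algebraic closure
                    term_rows.append(i)
                    term_k.append(kn)
            self.tables.append(
                dict(
                    mode=n,
                    col=col,
                    dn_rows=np.array(dn_rows, dtype=np.int64),
                    dn_pos=np.array(dn_pos, dtype=np.int64),
                    dn_k=np.array(dn_k, dtype=float),
                    up_rows=np.array(up_rows, dtype=np.int64),
                    up_pos=np.array(up_pos, dtype=np.int64),
                    term_rows=np.array(term_rows, dtype=np.int64),
                    term_k=np.array(term_k, dtype=float),
                )
            )
        self._assemble()

    def _assemble(self) -> None:
        """Flatten all time-independent couplings into one sparse matrix and
        collect the expectation-proportional parts per site."""
        import scipy.sparse as sp

        na, ns = self.n_aux, self.n_state
        dim = na * ns
        ms = self.modeset
        nonlin = self.variant != "linear"

        rows, cols, vals = [], [], []
        frows, fcols, fvals = [], [], []  # hierarchy flux terms only

        # Hamiltonian block: dphi[i,c] += (-i/hbar) H[c,c'] phi[i,c']
        hi, hc = np.nonzero(self.h_sub)
        for a, b in zip(hi, hc):
            i = np.arange(na)
            rows.append(i * ns + a)
            cols.append(i * ns + b)
            vals.append(np.full(na, (-1j / HBAR) * self.h_sub[a, b]))
        # hierarchy damping (all columns)
        i = np.arange(dim)
        rows.append(i)
        cols.append(i)
        vals.append(np.repeat(-self.depth_gamma / HBAR, ns))

        expect_entries: dict[int, list] = {int(s): [] for s in self.state_sites}
        for tab in self.tables:
            n = tab["mode"]
            col = tab["col"]
            site = int(ms.site[n])
            if tab["dn_rows"].size:
                coef = self._down_coef(n, tab["dn_k"])
                rows.append(tab["dn_rows"] * ns + col)
                cols.append(tab["dn_pos"] * ns + col)
                vals.append(coef)
                frows.append(tab["dn_rows"] * ns + col)
                fcols.append(tab["dn_pos"] * ns + col)
                fvals.append(coef)
            if tab["up_rows"].size:
                cu = self._up_coef(n)
                rows.append(tab["up_rows"] * ns + col)
                cols.append(tab["up_pos"] * ns + col)
                vals.append(np.full(tab["up_rows"].size, -cu))
                frows.append(tab["up_rows"] * ns + col)
                fcols.append(tab["up_pos"] * ns + col)
                fvals.append(np.full(tab["up_rows"].size, -cu))
                if nonlin:
                    # + cu <P_site> * full up-neighbor vector
                    for c in range(ns):
                        expect_entries[site].append(
                            (
                                tab["up_rows"] * ns + c,
                                tab["up_pos"] * ns + c,
                                np.full(tab["up_rows"].size, cu),
                            )
                        )
            if tab["term_rows"].size:
                q = self.depth_gamma[tab["term_rows"]] + ms.gamma[n]
                coef = (tab["term_k"] + 1.0) * ms.g[n] / (q * HBAR)
                rows.append(tab["term_rows"] * ns + col)
                cols.append(tab["term_rows"] * ns + col)
                vals.append(-coef)
                if nonlin:
                    expect_entries[site].append(
                        (tab["term_rows"] * ns + col, tab["term_rows"] * ns + col, coef)
                    )

        def build(r, c, v):
            return sp.csr_matrix(
                (np.concatenate(v), (np.concatenate(r), np.concatenate(c))),
                shape=(dim, dim),
                dtype=complex,
            )

        self._A = build(rows, cols, vals)
        if frows:
            self._A_flux = build(frows, fcols, fvals)
        else:
            import scipy.sparse as _sp
            self._A_flux = _sp.csr_matrix((dim, dim), dtype=complex)
        self._M_site = {}
        if nonlin:
            for site, entries in expect_entries.items():
                if entries:
                    r = [e[0] for e in entries]
                    c = [e[1] for e in entries]
                    v = [e[2] for e in entries]
                    self._M_site[site] = build(r, c, v)

    # -- coefficient helpers -------------------------------------------------
    def _down_coef(self, n: int, kvals: np.ndarray) -> np.ndarray:
        if self.variant == "normalized":
            return kvals * self.modeset.gamma[n] / HBAR
        return kvals * self.modeset.g[n] / HBAR

    def _up_coef(self, n: int) -> complex:
        if self.variant == "normalized":
            return self.modeset.g[n] / (self.modeset.gamma[n] * HBAR)
        return 1.0 / HBAR

    def expectations(self, phi: np.ndarray) -> np.ndarray:
        """<L_s^dag> per state column, from the normalized physical slice."""
        p0 = phi[0]
        nrm2 = float(np.real(np.vdot(p0, p0)))
        if nrm2 <= 0.0:
            raise ValueError("zero-norm physical wave function: expectation undefined")
        return np.abs(p0) ** 2 / nrm2

    def apply(
        self, phi: np.ndarray, zstar: np.ndarray, xi: np.ndarray,
        gamma_correction: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the time derivative.

        Parameters
        ----------
        phi : (n_aux, n_state) complex
        zstar : (n_sites_global,) complex — conjugated noise values z*_{s,t}
        xi : (n_modes_global,) complex — memory accumulators (ignored for the
            linear variant)
        gamma_correction : bool
            Include the scalar norm-preserving correction Gamma_t (normalized
            variant only).  Disabled when checking the adaptive derivative
            bound, which is defined on the flux terms alone.

        Returns ``(dphi, dxi)``.
        """
        ms = self.modeset
        nonlin = self.variant != "linear"

        if nonlin:
            expect = self.expectations(phi)  # per local column
        else:
            expect = None

        # effective noise per local column
        z_loc = zstar[self.state_sites].astype(complex)
        if nonlin:
            xi_by_site = np.zeros(self.system.n_sites, dtype=complex)
            np.add.at(xi_by_site, ms.site, xi)
            z_loc = z_loc + xi_by_site[self.state_sites]

        flat = phi.reshape(-1)
        dphi = (self._A @ flat).reshape(phi.shape)
        if nonlin:
            for c, s in enumerate(self.state_sites):
                M = self._M_site.get(int(s))
                if M is not None and expect[c] > 1e-300:
                    dphi += expect[c] * (M @ flat).reshape(phi.shape)
        dphi += phi * (z_loc / HBAR)[None, :]

        if nonlin:
            # memory drift (global, vectorized over all modes)
            p_by_site = np.zeros(self.system.n_sites)
            p_by_site[self.state_sites] = expect
            dxi = (-np.conj(ms.gamma) * xi + np.conj(ms.g) * p_by_site[ms.site]) / HBAR
        else:
            dxi = np.zeros_like(xi)

        if self.variant == "normalized" and gamma_correction:
            p0 = phi[0]
            nrm2 = float(np.real(np.vdot(p0, p0)))
            gamma_t = float(np.real(np.vdot(p0, dphi[0]))) / nrm2
            dphi -= gamma_t * phi

        return dphi, dxi

    def hierarchy_influx(self, phi: np.ndarray, expect: np.ndarray) -> np.ndarray:
        """Flux each slot receives from its hierarchy neighbors (the part of
        the derivative that survives when a slot's own amplitude is zeroed,
        apart from Hamiltonian mixing within the slot's own row)."""
        flat = phi.reshape(-1)
        out = (self._A_flux @ flat).reshape(phi.shape)
        if self.variant != "linear":
            for c, s in enumerate(self.state_sites):
                M = self._M_site.get(int(s))
                if M is not None and expect[c] > 1e-300:
                    out += expect[c] * (M @ flat).reshape(phi.shape)
        return out


# -- spec-surface wrappers ---------------------------------------------------

def _engine_for(state: HopsState, system, basis, modeset, variant, **kw):
    return DerivativeEngine(
        system, modeset, basis, state_sites=state.state_sites, variant=variant, **kw
    )


def linear_derivative(state, system, basis, modeset, zstar, **kw):
    """Linear HOPS derivative (see module docstring); returns (dphi, dxi)."""
    eng = _engine_for(state, system, basis, modeset, "linear", **kw)
    return eng.apply(state.wavefunctions, zstar, state.memory)


def nonlinear_derivative(state, system, basis, modeset, zstar, **kw):
    """Non-linear HOPS derivative with noise-memory drift."""
    eng = _engine_for(state, system, basis, modeset, "nonlinear", **kw)
    return eng.apply(state.wavefunctions, zstar, state.memory)


def normalized_derivative(state, system, basis, modeset, zstar, **kw):
    """Normalized non-linear HOPS derivative (k-dependent prefactor + Gamma_t)."""
    eng = _engine_for(state, system, basis, modeset, "normalized", **kw)
    return eng.apply(state.wavefunctions, zstar, state.memory)


def apply_terminator(state: HopsState, basis: HierarchyBasis, modeset: ModeSet,
                     k_max: int) -> dict:
    """Algebraic closures for up-neighbors absent past the depth bound.

    Returns ``{(aux, mode): closure_vector}`` in the state's own auxiliary
    scaling, valid when the auxiliary damping dominates system frequencies
    (k.gamma/hbar >> omega_sys).  With the closure substituted into the
    up-flux term, a k_max = 0 hierarchy reduces to Markovian quantum state
    diffusion.
    """
    out = {}
    markset = frozenset(np.nonzero(modeset.markovian)[0].tolist())
    for i, aux in enumerate(basis.members):
        if any(m in markset for m, _ in aux.pairs):
            continue
        if aux.depth_over(set(range(modeset.n_modes)) - markset) < k_max and k_max > 0:
            continue
        q = sum(k * modeset.gamma[m] for m, k in aux.pairs)
        for n in range(modeset.n_modes):
            if modeset.markovian[n]:
                continue
            if aux.plus(n) in basis:
                continue
            kn = aux.get(n)
            qq = q + modeset.gamma[n]
            col = np.nonzero(state.state_sites == modeset.site[n])[0]
            closure = np.zeros_like(state.wavefunctions[i])
            if col.size:
                closure[col[0]] = (kn + 1) * modeset.g[n] / qq * state.wavefunctions[i, col[0]]
            out[(aux, n)] = closure
    return out
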