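"""Adaptive auxiliary/state basis construction (adHOPS).

At each time point a reduced basis is built so that the Euclidean norm of
the difference between the full-basis time derivative and the derivative
evaluated in the reduced basis stays below a user threshold delta.  Because
the reduced state carries zero amplitude on excluded elements, that error is
exactly the flux the excluded slots would receive from the retained,
amplitude-carrying members — plus, for a member that is dropped outright,
its own derivative and its out-fluxes.  Exclusion candidates are ranked by
this squared flux and greedily removed smallest-first while the cumulative
squared error fits the budget; the total budget delta^2 is split equally in
quadrature between the auxiliary and state bases.

Site-projection coupling makes the bounds local: flux toward a higher
auxiliary through mode n only exists when the source has amplitude on
site n, and new sites can only be reached through off-diagonal Hamiltonian
elements.  The candidate pool is therefore the one-step neighborhood of the
current basis, so the construction cost scales with the occupied basis,
never with the aggregate size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .constants import HBAR
from .eom import DerivativeEngine, HopsState, ModeSet
from .hierarchy import AuxIndex, HierarchyBasis, markovian_valid, triangular_basis
from .system import SystemModel

__all__ = ["AdaptiveBasis", "flux_up_bounds", "build_adaptive_basis", "rebase_state"]

_OCCUPIED_EPS = 1e-12  # physical amplitude above this pins a site in the basis


@dataclass
class AdaptiveBasis:
    """Reduced auxiliary and state bases with their error budgets."""

    aux_set: HierarchyBasis
    state_set: np.ndarray
    delta_aux: float
    delta_state: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if AuxIndex.zero() not in self.aux_set:
            raise ValueError("adaptive basis must retain the physical wave function")


def _out_of_basis_influx(
    engine: DerivativeEngine,
    phi: np.ndarray,
    expect: np.ndarray,
    markset: frozenset[int],
    k_max: int,
) -> dict[AuxIndex, np.ndarray]:
    """Derivative vectors every out-of-basis one-step neighbor would receive
    from the current members, accumulated in one pass over the members.

    The squared norm of each vector is the candidate's exact exclusion
    error — a tight upper bound on any subset of its source terms.
    """
    ms = engine.modeset
    pos = engine.basis.position
    acc: dict[AuxIndex, np.ndarray] = {}
    members = engine.basis.members
    n_state = engine.n_state
    for n in engine.active_modes:
        n = int(n)
        col = engine.site_to_col[int(ms.site[n])]
        if engine.variant == "normalized":
            base_dn = ms.gamma[n] / HBAR
        else:
            base_dn = ms.g[n] / HBAR
        cu = engine._up_coef(n)
        for i, aux in enumerate(members):
            # member feeds its (absent) up-neighbor via the down-flux term
            amp = phi[i, col]
            if amp != 0.0:
                up = aux.plus(n)
                if up not in pos and markovian_valid(up, markset, k_max):
                    vec = acc.get(up)
                    if vec is None:
                        vec = np.zeros(n_state, dtype=complex)
                        acc[up] = vec
                    vec[col] += (aux.get(n) + 1) * base_dn * amp
            # member feeds its (absent) down-neighbor via the up-flux term
            down = aux.minus(n)
            if down is not None and down not in pos:
                vec = acc.get(down)
                if vec is None:
                    vec = np.zeros(n_state, dtype=complex)
                    acc[down] = vec
                vec += (cu * expect[col]) * phi[i, :]
                vec[col] -= cu * amp
    return acc


def flux_up_bounds(
    state: HopsState,
    system: SystemModel,
    modeset: ModeSet,
    candidates: list[AuxIndex],
    variant: str = "normalized",
) -> np.ndarray:
    """Squared flux each out-of-basis auxiliary would receive from the state.

    The bound is tight (it is the exact squared norm of the summed
    contributions), non-negative, and zero for candidates reachable only via
    modes of unpopulated sites.
    """
    engine = DerivativeEngine(
        system, modeset, state.basis, state_sites=state.state_sites, variant=variant
    )
    phi = state.wavefunctions
    expect = engine.expectations(phi) if variant != "linear" else np.zeros(engine.n_state)
    ms = engine.modeset
    pos = engine.basis.position
    out = np.zeros(len(candidates))
    for idx, cand in enumerate(candidates):
        vec = np.zeros(engine.n_state, dtype=complex)
        for n in engine.active_modes:
            n = int(n)
            col = engine.site_to_col[int(ms.site[n])]
            kn = cand.get(n)
            if kn:
                below = cand.minus(n)
                j = pos.get(below)
                if j is not None:
                    if variant == "normalized":
                        coef = kn * ms.gamma[n] / HBAR
                    else:
                        coef = kn * ms.g[n] / HBAR
                    vec[col] += coef * phi[j, col]
            j = pos.get(cand.plus(n))
            if j is not None:
                cu = engine._up_coef(n)
                vec[col] -= cu * phi[j, col]
                vec += (cu * expect[col]) * phi[j, :]
        out[idx] = float(np.real(np.vdot(vec, vec)))
    return out


def build_adaptive_basis(
    state: HopsState,
    system: SystemModel,
    modeset: ModeSet,
    k_max: int,
    delta: float,
    zstar: np.ndarray | None = None,
    aux_state_split: float = 0.5,
    engine: DerivativeEngine | None = None,
) -> AdaptiveBasis:
    """Greedy reduced-basis selection with derivative-error budget ``delta``.

    ``aux_state_split`` is the fraction of delta^2 assigned to the auxiliary
    basis (the remainder bounds the state-basis error).  ``delta = 0``
    reverts to the full triangular basis over every mode and every site.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    markmask = modeset.markovian
    if delta == 0.0:
        full = triangular_basis(modeset.n_modes, k_max, markmask)
        return AdaptiveBasis(
            aux_set=full,
            state_set=np.arange(system.n_sites),
            delta_aux=0.0,
            delta_state=0.0,
            time=state.time,
        )

    budget_aux = delta**2 * aux_state_split
    budget_state = delta**2 * (1.0 - aux_state_split)
    markset = frozenset(np.nonzero(markmask)[0].tolist())

    if engine is None or engine.basis is not state.basis:
        engine = DerivativeEngine(
            system, modeset, state.basis, state_sites=state.state_sites,
            variant="normalized",
        )
    phi = state.wavefunctions
    expect = engine.expectations(phi)
    if zstar is None:
        zstar = np.zeros(system.n_sites, dtype=complex)
    dphi, _ = engine.apply(phi, zstar, state.memory)

    members = engine.basis.members

    # --- auxiliary basis ----------------------------------------------------
    cand_vecs = _out_of_basis_influx(engine, phi, expect, markset, k_max)
    candidates = list(cand_vecs)
    cand_flux = np.array(
        [float(np.real(np.vdot(v, v))) for v in cand_vecs.values()]
    )

    # exclusion cost of a currently-retained member: the flux it receives
    # from its neighbors (what the defining bound sees once its amplitude is
    # zeroed), its own dynamics, and its out-fluxes into retained slots
    influx = engine.hierarchy_influx(phi, expect)
    own = dphi - influx
    member_flux = np.real(
        np.einsum("ij,ij->i", influx.conj(), influx)
        + np.einsum("ij,ij->i", own.conj(), own)
    )
    amp2 = np.abs(phi) ** 2
    for tab in engine.tables:
        n = tab["mode"]
        col = tab["col"]
        cu = abs(engine._up_coef(n)) ** 2
        row_amp2 = amp2.sum(axis=1)
        # up out-flux: |cu|^2 * ||(P_n - <P_n>) phi||^2 for rows whose up-neighbor is retained
        if tab["up_rows"].size:
            r = tab["up_rows"]
            opn = (1.0 - expect[col]) ** 2 * amp2[r, col] + expect[col] ** 2 * (
                row_amp2[r] - amp2[r, col]
            )
            member_flux[r] += cu * opn
        if tab["dn_rows"].size:
            r = tab["dn_rows"]
            if engine.variant == "normalized":
                cd = np.abs(tab["dn_k"] * engine.modeset.gamma[n] / HBAR) ** 2
            else:
                cd = np.abs(tab["dn_k"] * engine.modeset.g[n] / HBAR) ** 2
            member_flux[r] += cd * amp2[r, col]

    entries = []
    for aux, f2 in zip(candidates, cand_flux):
        entries.append((f2, aux, False))
    for i, aux in enumerate(members):
        if i == 0:
            continue  # physical wave function is always retained
        entries.append((float(member_flux[i]), aux, True))
    entries.sort(key=lambda e: (e[0], e[1]))

    kept_aux = {AuxIndex.zero()}
    acc = 0.0
    excluded_done = False
    for f2, aux, is_member in entries:
        if not excluded_done and acc + f2 <= budget_aux:
            acc += f2
        else:
            excluded_done = True
            kept_aux.add(aux)

    # --- state basis ----------------------------------------------------------
    cur_sites = engine.state_sites
    neighbor_sites = system.coupled_sites(cur_sites)
    all_sites = np.union1d(cur_sites, neighbor_sites)
    site_flux = {}
    h = system.hamiltonian
    col_amp2 = amp2.sum(axis=0)
    phys_amp2 = np.abs(phi[0]) ** 2
    for s in all_sites:
        s = int(s)
        if s in engine.site_to_col:
            col = engine.site_to_col[s]
            if phys_amp2[col] > _OCCUPIED_EPS:
                site_flux[s] = np.inf  # occupied sites are never dropped
                continue
            f2 = float(np.sum(np.abs(dphi[:, col]) ** 2))
            hcol = _h_column(h, s, cur_sites)
            f2 += float(np.sum(np.abs(hcol) ** 2)) / HBAR**2 * float(col_amp2[col])
            site_flux[s] = f2
        else:
            # influx into an empty site via H off-diagonals
            hrow = _h_column(h, s, cur_sites)
            mix = phi @ (hrow / HBAR)
            site_flux[s] = float(np.sum(np.abs(mix) ** 2))
    s_entries = sorted(site_flux.items(), key=lambda kv: (kv[1], kv[0]))
    kept_sites = []
    acc = 0.0
    excluded_done = False
    for s, f2 in s_entries:
        if not excluded_done and acc + f2 <= budget_state:
            acc += f2
        else:
            excluded_done = True
            kept_sites.append(s)

    return AdaptiveBasis(
        aux_set=HierarchyBasis(kept_aux),
        state_set=np.array(sorted(kept_sites), dtype=np.int64),
        delta_aux=float(np.sqrt(budget_aux)),
        delta_state=float(np.sqrt(budget_state)),
        time=state.time,
    )


def _h_column(h, s: int, sites: np.ndarray) -> np.ndarray:
    """Off-diagonal H elements connecting site ``s`` to ``sites``."""
    if sp.issparse(h):
        col = np.asarray(h[sites, s].todense()).ravel().astype(complex)
    else:
        col = np.asarray(h[sites, s], dtype=complex)
    col[sites == s] = 0.0
    return col


def rebase_state(state: HopsState, new_basis: HierarchyBasis,
                 new_sites: np.ndarray) -> HopsState:
    """Carry amplitudes onto a new basis by (auxiliary, site) identity.

    New slots start at zero; dropped slots are discarded (their flux was
    within the adaptive budget).  The memory accumulators are global and
    carry over unchanged.
    """
    new_sites = np.asarray(sorted(new_sites), dtype=np.int64)
    old_sites = state.state_sites
    phi_new = np.zeros((len(new_basis), len(new_sites)), dtype=complex)
    common_sites, old_cols, new_cols = np.intersect1d(
        old_sites, new_sites, return_indices=True
    )
    old_pos = state.basis.position
    for i, aux in enumerate(new_basis.members):
        j = old_pos.get(aux)
        if j is not None:
            phi_new[i, new_cols] = state.wavefunctions[j, old_cols]
    return HopsState(
        wavefunctions=phi_new,
        memory=state.memory.copy(),
        time=state.time,
        basis=new_basis,
        state_sites=new_sites,
    )
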