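"""Single stochastic-trajectory integration.

A trajectory draws one realization of the per-site colored noise, then
steps the chosen HOPS variant with classical fixed-step fourth-order
Runge-Kutta (noise linearly interpolated at half steps).  For the adaptive
variant the reduced auxiliary/state basis is rebuilt from the current state
once per step, before the step, and all four stage derivatives are
evaluated in that basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .adaptivity import build_adaptive_basis, rebase_state
from .bath import DrudeLorentzBath
from .eom import DerivativeEngine, HopsState, ModeSet
from .hierarchy import AuxIndex, HierarchyBasis, triangular_basis
from .noise import NoiseTrajectory, generate_noise, noise_at_all
from .system import SystemModel

__all__ = ["RunConfig", "TrajectoryResult", "SimulationContext", "initial_state",
           "integrate"]

_VARIANTS = ("linear", "nonlinear", "normalized", "adaptive")


@dataclass
class RunConfig:
    """Complete description of one simulation run.

    Chain shorthand: ``n_sites`` sites with uniform ``site_energy``,
    nearest-neighbor coupling ``coupling`` (cm^-1) and spacing ``l_0``;
    alternatively pass an explicit ``hamiltonian``.  One Drude-Lorentz bath
    per site.  ``variant='adaptive'`` runs the normalized equation in the
    delta-bounded reduced basis.
    """

    n_sites: int = 2
    coupling: float = 50.0
    site_energy: float = 0.0
    l_0: float = 1.0
    hamiltonian: np.ndarray | None = None

    lambda_reorg: float = 50.0
    bath_gamma: float = 50.0
    temperature: float = 295.0
    gamma_mark: float | None = 500.0
    baths: list | None = None  # explicit per-site baths (None entry = no bath)

    variant: str = "normalized"
    k_max: int = 4
    delta: float = 0.0
    aux_state_split: float = 0.5

    dt: float = 2.0
    t_max: float = 200.0
    seed: int = 0
    n_traj: int = 100
    terminator: bool = False
    start_site: int | None = None
    initial_amplitudes: np.ndarray | None = None  # overrides start_site
    store_every: int = 1
    aux_capture: Sequence = ()

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max < self.dt:
            raise ValueError("t_max must be at least dt")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    def build_system(self) -> SystemModel:
        if self.hamiltonian is not None:
            return SystemModel(self.hamiltonian)
        from .fixtures import ChainSpec, build_chain

        return build_chain(
            ChainSpec(
                n_sites=self.n_sites,
                coupling=self.coupling,
                site_energy=self.site_energy,
                l_0=self.l_0,
            )
        )

    def build_baths(self) -> list[DrudeLorentzBath]:
        if self.baths is not None:
            return list(self.baths)
        n = self.n_sites if self.hamiltonian is None else self.hamiltonian.shape[0]
        return [
            DrudeLorentzBath(
                lambda_reorg=self.lambda_reorg,
                gamma=self.bath_gamma,
                temperature=self.temperature,
                gamma_mark=self.gamma_mark,
            )
            for _ in range(n)
        ]

    def build_modeset(self) -> ModeSet:
        return ModeSet.from_baths(self.build_baths())

    @property
    def resolved_start_site(self) -> int:
        n = self.n_sites if self.hamiltonian is None else self.hamiltonian.shape[0]
        s = n // 2 if self.start_site is None else self.start_site
        if not 0 <= s < n:
            raise ValueError(f"start site {s} out of range for {n} sites")
        return s

    def time_axis(self) -> np.ndarray:
        n_steps = int(round(self.t_max / self.dt))
        return np.arange(n_steps + 1) * self.dt


@dataclass
class TrajectoryResult:
    """Stored time series of one stochastic trajectory."""

    t: np.ndarray
    psi: np.ndarray  # (n_stored, n_sites) physical wave function (global sites)
    norms: np.ndarray  # physical-slice norm before normalization (linear variant)
    aux_sizes: np.ndarray
    state_sizes: np.ndarray
    memory: np.ndarray
    seed: int
    normalized: bool
    aux_capture: dict = field(default_factory=dict)
    diverged: bool = False

    def populations(self) -> np.ndarray:
        p = np.abs(self.psi) ** 2
        nrm = p.sum(axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        return p / nrm


def initial_state(
    config: RunConfig,
    basis: HierarchyBasis | None = None,
    state_sites: np.ndarray | None = None,
    modeset: ModeSet | None = None,
) -> HopsState:
    """Excitation localized on the start site; all auxiliaries and memory zero."""
    modeset = modeset or config.build_modeset()
    n = config.n_sites if config.hamiltonian is None else config.hamiltonian.shape[0]
    if config.initial_amplitudes is not None:
        amps = np.asarray(config.initial_amplitudes, dtype=complex)
        if amps.shape != (n,):
            raise ValueError("initial_amplitudes must have one entry per site")
        nrm = np.linalg.norm(amps)
        if nrm == 0:
            raise ValueError("initial amplitudes are all zero")
        amps = amps / nrm
        occupied = np.nonzero(np.abs(amps) > 0)[0]
    else:
        start = config.resolved_start_site
        amps = np.zeros(n, dtype=complex)
        amps[start] = 1.0
        occupied = np.array([start], dtype=np.int64)
    if config.variant == "adaptive":
        if basis is None:
            basis = HierarchyBasis([AuxIndex.zero()])
        if state_sites is None:
            state_sites = occupied
    else:
        if basis is None:
            basis = triangular_basis(modeset.n_modes, config.k_max, modeset.markovian)
        if state_sites is None:
            state_sites = np.arange(n)
    state_sites = np.asarray(sorted(state_sites), dtype=np.int64)
    phi = np.zeros((len(basis), len(state_sites)), dtype=complex)
    phi[0] = amps[state_sites]
    return HopsState(
        wavefunctions=phi,
        memory=np.zeros(modeset.n_modes, dtype=complex),
        time=0.0,
        basis=basis,
        state_sites=state_sites,
    )


class SimulationContext:
    """Per-run immutable objects shared across an ensemble's trajectories:
    the system, the mode set, and (for fixed-basis variants) the full
    triangular basis with its prebuilt derivative engine."""

    def __init__(self, config: RunConfig):
        self.system = config.build_system()
        self.modeset = config.build_modeset()
        self.engine = None
        self.basis = None
        if config.variant != "adaptive":
            self.basis = triangular_basis(
                self.modeset.n_modes, config.k_max, self.modeset.markovian
            )
            self.engine = DerivativeEngine(
                self.system,
                self.modeset,
                self.basis,
                variant=config.variant,
                k_max=config.k_max,
                terminator=config.terminator,
            )


def integrate(config: RunConfig, traj_seed: int,
              noise: NoiseTrajectory | None = None,
              context: SimulationContext | None = None) -> TrajectoryResult:
    """Integrate one trajectory; deterministic given (config, traj_seed)."""
    if context is None:
        context = SimulationContext(config)
    system = context.system
    modeset = context.modeset
    t_axis = config.time_axis()
    if noise is None:
        noise = generate_noise(modeset.modes, t_axis, traj_seed, n_sites=system.n_sites)
    adaptive = config.variant == "adaptive"
    eom_variant = "normalized" if adaptive else config.variant
    renorm = eom_variant == "normalized"
    # the reduced density matrix averages normalized projectors for both
    # nonlinear forms; only the linear variant is norm-weighted
    store_normalized = eom_variant in ("nonlinear", "normalized")

    state = initial_state(config, basis=context.basis, modeset=modeset)
    engine = context.engine
    engine_key = None if engine is None else (
        len(state.basis), hash(tuple(state.basis.members)), state.state_sites.tobytes()
    )

    capture_keys = [
        a if isinstance(a, AuxIndex) else AuxIndex.from_dense(a)
        for a in config.aux_capture
    ]
    captured = {k: [] for k in capture_keys}

    n_steps = len(t_axis) - 1
    stored_t, stored_psi, stored_norm = [], [], []
    aux_sizes, state_sizes = [], []
    n_sites = system.n_sites
    dt = config.dt
    diverged = False

    def record(state: HopsState) -> None:
        psi_glob = np.zeros(n_sites, dtype=complex)
        psi_glob[state.state_sites] = state.wavefunctions[0]
        nrm = float(np.linalg.norm(psi_glob))
        stored_norm.append(nrm)
        if store_normalized and nrm > 0:
            psi_glob = psi_glob / nrm
        stored_psi.append(psi_glob)
        stored_t.append(state.time)
        aux_sizes.append(len(state.basis))
        state_sizes.append(len(state.state_sites))
        for key in capture_keys:
            j = state.basis.position.get(key)
            captured[key].append(
                float(np.sum(np.abs(state.wavefunctions[j]) ** 2)) if j is not None else 0.0
            )

    for step in range(n_steps + 1):
        t = t_axis[step]
        state.time = float(t)
        if adaptive:
            zs = np.conj(noise_at_all(noise, t))
            ab = build_adaptive_basis(
                state,
                system,
                modeset,
                config.k_max,
                config.delta,
                zstar=zs,
                aux_state_split=config.aux_state_split,
                engine=engine if engine is not None and engine.basis is state.basis
                and engine.variant == "normalized" else None,
            )
            same = (
                len(ab.aux_set) == len(state.basis)
                and np.array_equal(ab.state_set, state.state_sites)
                and ab.aux_set.members == state.basis.members
            )
            if not same:
                state = rebase_state(state, ab.aux_set, ab.state_set)
        if step % config.store_every == 0 or step == n_steps:
            record(state)
        if step == n_steps:
            break

        key = (len(state.basis), hash(tuple(state.basis.members)),
               state.state_sites.tobytes())
        if key != engine_key:
            engine = DerivativeEngine(
                system,
                modeset,
                state.basis,
                state_sites=state.state_sites,
                variant=eom_variant,
                k_max=config.k_max,
                terminator=config.terminator,
            )
            engine_key = key

        z0 = np.conj(noise_at_all(noise, t))
        zh = np.conj(noise_at_all(noise, t + dt / 2.0))
        z1 = np.conj(noise_at_all(noise, t + dt))
        phi, xi = state.wavefunctions, state.memory
        k1, m1 = engine.apply(phi, z0, xi)
        k2, m2 = engine.apply(phi + 0.5 * dt * k1, zh, xi + 0.5 * dt * m1)
        k3, m3 = engine.apply(phi + 0.5 * dt * k2, zh, xi + 0.5 * dt * m2)
        k4, m4 = engine.apply(phi + dt * k3, z1, xi + dt * m3)
        phi = phi + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        xi = xi + (dt / 6.0) * (m1 + 2.0 * m2 + 2.0 * m3 + m4)

        if not np.all(np.isfinite(phi)):
            if eom_variant == "linear":
                diverged = True  # linear-variant norms can blow up; flag and stop
                state.wavefunctions = phi
                break
            raise RuntimeError(
                f"non-finite amplitudes at t={t + dt:.2f} fs "
                f"(variant={eom_variant}, basis size {len(state.basis)})"
            )
        if renorm:
            # project back onto the unit-physical-norm manifold; the
            # continuous-time equation conserves the norm exactly
            nrm = float(np.linalg.norm(phi[0]))
            if nrm > 0:
                phi = phi / nrm
        state = HopsState(
            wavefunctions=phi,
            memory=xi,
            time=float(t_axis[step + 1]),
            basis=state.basis,
            state_sites=state.state_sites,
        )

    return TrajectoryResult(
        t=np.array(stored_t),
        psi=np.array(stored_psi),
        norms=np.array(stored_norm),
        aux_sizes=np.array(aux_sizes),
        state_sizes=np.array(state_sizes),
        memory=state.memory,
        seed=traj_seed,
        normalized=store_normalized,
        aux_capture={tuple(k.pairs): np.array(v) for k, v in captured.items()},
        diverged=diverged,
    )
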