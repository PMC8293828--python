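import numpy as np
import pytest

from adhops.adaptivity import (
    AdaptiveBasis,
    build_adaptive_basis,
    flux_up_bounds,
    rebase_state,
)
from adhops.eom import DerivativeEngine, HopsState, ModeSet
from adhops.hierarchy import AuxIndex, HierarchyBasis, triangular_basis
from adhops.noise import generate_noise, noise_at_all
from adhops.trajectory import RunConfig, initial_state, integrate
from adhops.ensemble import adaptive_error, run_ensemble


def embed_state(state, full_basis, n_sites):
    phi = np.zeros((len(full_basis), n_sites), dtype=complex)
    for i, aux in enumerate(state.basis.members):
        phi[full_basis.position[aux], state.state_sites] = state.wavefunctions[i]
    return phi


@pytest.fixture
def dimer_setup(bath):
    cfg = RunConfig(n_sites=2, coupling=50.0, variant="normalized", k_max=2,
                    dt=2.0, t_max=50.0)
    system = cfg.build_system()
    ms = cfg.build_modeset()
    return cfg, system, ms


def random_partial_state(system, ms, k_max, keep, seed=0):
    full = triangular_basis(ms.n_modes, k_max, ms.markovian)
    rng = np.random.default_rng(seed)
    sub = HierarchyBasis([full.members[i] for i in keep])
    phi = rng.standard_normal((len(sub), system.n_sites)) + 1j * rng.standard_normal(
        (len(sub), system.n_sites)
    )
    phi[0] /= np.linalg.norm(phi[0])
    st = HopsState(phi, np.zeros(ms.n_modes, complex), 0.0, sub,
                   np.arange(system.n_sites))
    return full, sub, st


class TestFluxBounds:
    def test_equals_brute_force_excluded_derivative(self, dimer_setup):
        """The bound for each excluded auxiliary is exactly the squared norm
        of the full-basis derivative restricted to its slot when the
        retained-state derivative is zeroed out."""
        _, system, ms = dimer_setup
        full, sub, st = random_partial_state(system, ms, 2, [0, 1, 2, 3, 4, 5])
        excluded = [a for a in full.members if a not in sub]
        bounds = flux_up_bounds(st, system, ms, excluded)
        eng = DerivativeEngine(system, ms, full, variant="normalized")
        phi_emb = embed_state(st, full, system.n_sites)
        d_full, _ = eng.apply(phi_emb, np.zeros(2, complex),
                              np.zeros(ms.n_modes, complex))
        brute = np.array(
            [np.sum(np.abs(d_full[full.position[a]]) ** 2) for a in excluded]
        )
        np.testing.assert_allclose(bounds, brute, rtol=1e-10)

    def test_zero_for_candidates_of_unpopulated_sites(self, dimer_setup):
        _, system, ms = dimer_setup
        cfg = RunConfig(n_sites=2, coupling=50.0, variant="normalized", k_max=2)
        st = initial_state(cfg, modeset=ms)  # everything on site 1
        site0_modes = ms.modes_of_sites([0])
        cands = [AuxIndex.unit(int(n)) for n in site0_modes]
        bounds = flux_up_bounds(st, system, ms, cands)
        np.testing.assert_allclose(bounds, 0.0, atol=1e-300)

    def test_nonnegative_and_monotone_in_amplitude(self, dimer_setup):
        _, system, ms = dimer_setup
        full, sub, st = random_partial_state(system, ms, 2, [0, 1, 2, 3])
        excluded = [a for a in full.members if a not in sub]
        b1 = flux_up_bounds(st, system, ms, excluded)
        assert np.all(b1 >= 0)
        st.wavefunctions[1:] *= 2.0  # scale non-physical amplitudes up
        b2 = flux_up_bounds(st, system, ms, excluded)
        assert np.all(b2 >= b1 - 1e-12)


class TestBuildAdaptiveBasis:
    def test_delta_zero_reverts_to_full_hops(self, dimer_setup):
        cfg, system, ms = dimer_setup
        st = initial_state(cfg, modeset=ms)
        ab = build_adaptive_basis(st, system, ms, cfg.k_max, 0.0)
        assert len(ab.aux_set) == len(
            triangular_basis(ms.n_modes, cfg.k_max, ms.markovian)
        )
        np.testing.assert_array_equal(ab.state_set, np.arange(2))

    def test_huge_delta_keeps_only_occupied_elements(self):
        cfg = RunConfig(n_sites=5, coupling=50.0, variant="adaptive", k_max=4,
                        delta=10.0, dt=2.0, t_max=60.0)
        res = integrate(cfg, 3)
        # with an enormous budget nothing but the physical slice survives,
        # so the excitation never leaves the initial site
        assert res.aux_sizes.max() == 1
        assert res.state_sizes.max() == 1
        np.testing.assert_allclose(res.populations()[-1, 2], 1.0, atol=1e-12)

    def test_negative_delta_rejected(self, dimer_setup):
        cfg, system, ms = dimer_setup
        st = initial_state(cfg, modeset=ms)
        with pytest.raises(ValueError):
            build_adaptive_basis(st, system, ms, cfg.k_max, -1.0)

    def test_derivative_error_bounded_along_trajectory(self):
        """Defining property: the distance between the full-basis derivative
        of the embedded state and the reduced-basis derivative stays below
        delta at every step (Gamma_t correction excluded, as the bound is
        defined on the flux terms)."""
        delta = 1e-4
        cfg = RunConfig(n_sites=3, coupling=50.0, variant="adaptive", k_max=4,
                        delta=delta, dt=2.0, t_max=100.0)
        system, ms = cfg.build_system(), cfg.build_modeset()
        t_axis = cfg.time_axis()
        noise = generate_noise(ms.modes, t_axis, 3, n_sites=3)
        full = triangular_basis(ms.n_modes, cfg.k_max, ms.markovian)
        full_eng = DerivativeEngine(system, ms, full, variant="normalized")
        state = initial_state(cfg, modeset=ms)
        maxerr = 0.0
        for step in range(len(t_axis) - 1):
            t = t_axis[step]
            zs = np.conj(noise_at_all(noise, t))
            ab = build_adaptive_basis(state, system, ms, cfg.k_max, delta, zstar=zs)
            state = rebase_state(state, ab.aux_set, ab.state_set)
            eng = DerivativeEngine(system, ms, state.basis, state.state_sites,
                                   "normalized")
            phi_emb = embed_state(state, full, 3)
            d_full, _ = full_eng.apply(phi_emb, zs, state.memory,
                                       gamma_correction=False)
            d_ad, _ = eng.apply(state.wavefunctions, zs, state.memory,
                                gamma_correction=False)
            d_emb = np.zeros_like(phi_emb)
            for i, aux in enumerate(state.basis.members):
                d_emb[full.position[aux], state.state_sites] = d_ad[i]
            maxerr = max(maxerr, float(np.linalg.norm(d_full - d_emb)))
            # advance on the reduced basis (RK4, shared noise)
            zh = np.conj(noise_at_all(noise, t + 1.0))
            z1 = np.conj(noise_at_all(noise, t + 2.0))
            phi, xi = state.wavefunctions, state.memory
            k1, m1 = eng.apply(phi, zs, xi)
            k2, m2 = eng.apply(phi + k1, zh, xi + m1)
            k3, m3 = eng.apply(phi + k2, zh, xi + m2)
            k4, m4 = eng.apply(phi + 2 * k3, z1, xi + 2 * m3)
            phi = phi + (k1 + 2 * k2 + 2 * k3 + k4) / 3.0
            xi = xi + (m1 + 2 * m2 + 2 * m3 + m4) / 3.0
            phi /= np.linalg.norm(phi[0])
            state = HopsState(phi, xi, t + 2.0, state.basis, state.state_sites)
        assert maxerr <= delta

    def test_error_decreases_with_delta(self, bath):
        """Coarse adaptive-error curve: populations improve monotonically as
        the derivative bound tightens (small shared-noise ensemble)."""
        kw = dict(n_sites=5, coupling=50.0, k_max=6, dt=2.0, t_max=100.0)
        hops = run_ensemble(RunConfig(variant="normalized", **kw), 25, 1)
        errs = []
        for d in (1e-1, 1e-2, 1e-3):
            ad = run_ensemble(RunConfig(variant="adaptive", delta=d, **kw), 25, 1)
            errs.append(adaptive_error(ad, hops))
        assert errs[0] > errs[1] > errs[2]


class TestRebase:
    def test_identity_on_identical_bases(self, dimer_setup):
        cfg, system, ms = dimer_setup
        st = initial_state(cfg, modeset=ms)
        st2 = rebase_state(st, st.basis, st.state_sites)
        np.testing.assert_array_equal(st2.wavefunctions, st.wavefunctions)

    def test_grown_slot_starts_at_zero(self, dimer_setup):
        cfg, system, ms = dimer_setup
        small = HierarchyBasis([AuxIndex.zero()])
        st = initial_state(cfg, basis=small, modeset=ms)
        grown = HierarchyBasis([AuxIndex.zero(), AuxIndex.unit(0)])
        st2 = rebase_state(st, grown, st.state_sites)
        np.testing.assert_array_equal(st2.wavefunctions[1], 0.0)
        np.testing.assert_array_equal(st2.wavefunctions[0], st.wavefunctions[0])

    def test_drop_and_readd_zero_amplitude_roundtrips(self, dimer_setup):
        cfg, system, ms = dimer_setup
        big = HierarchyBasis([AuxIndex.zero(), AuxIndex.unit(0), AuxIndex.unit(2)])
        st = initial_state(cfg, basis=big, modeset=ms)
        small = HierarchyBasis([AuxIndex.zero(), AuxIndex.unit(0)])
        back = rebase_state(rebase_state(st, small, st.state_sites), big,
                            st.state_sites)
        np.testing.assert_array_equal(back.wavefunctions, st.wavefunctions)

    def test_physical_index_cannot_be_dropped(self):
        # a hierarchy basis without the zero index is unrepresentable
        with pytest.raises(ValueError):
            HierarchyBasis([AuxIndex.unit(0)])
        # and an AdaptiveBasis always carries it
        ok = AdaptiveBasis(
            aux_set=HierarchyBasis([AuxIndex.zero()]),
            state_set=np.array([0]),
            delta_aux=0.0,
            delta_state=0.0,
        )
        assert AuxIndex.zero() in ok.aux_set


def test_adaptive_aux_basis_subset_of_triangular():
    cfg = RunConfig(n_sites=3, coupling=50.0, variant="adaptive", k_max=3,
                    delta=1e-3, dt=2.0, t_max=80.0)
    system, ms = cfg.build_system(), cfg.build_modeset()
    t_axis = cfg.time_axis()
    noise = generate_noise(ms.modes, t_axis, 5, n_sites=3)
    full = triangular_basis(ms.n_modes, cfg.k_max, ms.markovian)
    state = initial_state(cfg, modeset=ms)
    for step in range(20):
        zs = np.conj(noise_at_all(noise, t_axis[step]))
        ab = build_adaptive_basis(state, system, ms, cfg.k_max, cfg.delta, zstar=zs)
        assert all(a in full for a in ab.aux_set.members)
        state = rebase_state(state, ab.aux_set, ab.state_set)
        state.wavefunctions[0, 0] = 1.0  # keep a valid physical slice
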