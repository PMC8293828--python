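import numpy as np
import pytest

from adhops.bath import DrudeLorentzBath
from adhops.constants import HBAR
from adhops.eom import (
    DerivativeEngine,
    HopsState,
    ModeSet,
    apply_terminator,
    linear_derivative,
)
from adhops.fixtures import dephasing_oracle
from adhops.hierarchy import AuxIndex, triangular_basis
from adhops.noise import generate_noise, noise_at_all
from adhops.system import SystemModel
from adhops.trajectory import RunConfig, integrate
from adhops.ensemble import bootstrap_se, run_ensemble


def make_state(modeset, basis, n_sites, amps=None):
    phi = np.zeros((len(basis), n_sites), dtype=complex)
    if amps is None:
        phi[0, 0] = 1.0
    else:
        phi[0] = amps
    return HopsState(phi, np.zeros(modeset.n_modes, complex), 0.0, basis,
                     np.arange(n_sites))


class TestLinearEquation:
    def test_isolated_site_evolves_by_phase_only(self, bath):
        """With zero noise and no coupling the physical slice picks up the
        bare phase -i eps/hbar and feeds only its first-order auxiliary."""
        ms = ModeSet.from_baths([bath])
        basis = triangular_basis(ms.n_modes, 2, ms.markovian)
        sys1 = SystemModel(np.array([[120.0]]))
        st = make_state(ms, basis, 1)
        d, _ = linear_derivative(st, sys1, basis, ms, np.zeros(1, complex))
        assert d[0, 0] == pytest.approx(-1j * 120.0 / HBAR)

    def test_linearity_in_the_state(self, bath):
        ms = ModeSet.from_baths([bath, bath])
        basis = triangular_basis(ms.n_modes, 2, ms.markovian)
        sys2 = SystemModel(np.array([[0.0, 50.0], [50.0, 0.0]]))
        eng = DerivativeEngine(sys2, ms, basis, variant="linear")
        rng = np.random.default_rng(3)
        z = rng.standard_normal(2) + 1j * rng.standard_normal(2)
        xi = np.zeros(ms.n_modes, complex)
        a = rng.standard_normal((len(basis), 2)) + 1j * rng.standard_normal((len(basis), 2))
        b = rng.standard_normal((len(basis), 2)) + 1j * rng.standard_normal((len(basis), 2))
        da, _ = eng.apply(a, z, xi)
        db, _ = eng.apply(b, z, xi)
        dab, _ = eng.apply(1.7 * a - 0.3j * b, z, xi)
        np.testing.assert_allclose(dab, 1.7 * da - 0.3j * db, rtol=1e-12, atol=1e-12)

    def test_pure_dephasing_conserves_ensemble_populations(self, bath):
        """Without electronic coupling the bath only dephases: individual
        trajectories diffuse but the ensemble-mean populations are frozen."""
        cfg = RunConfig(hamiltonian=np.diag([0.0, 80.0]), baths=[bath, bath],
                        variant="normalized", k_max=4, dt=2.0, t_max=100.0,
                        initial_amplitudes=np.array([0.6, 0.8]))
        ens = run_ensemble(cfg, n_traj=150, master_seed=4)
        se = bootstrap_se(ens, 100, 0)
        dev = np.abs(ens.populations - ens.populations[0])
        assert np.max(dev / np.maximum(3 * se, 1e-3)) < 1.0


class TestNonlinearEquation:
    def test_zero_norm_physical_slice_rejected(self, bath):
        ms = ModeSet.from_baths([bath])
        basis = triangular_basis(ms.n_modes, 2, ms.markovian)
        eng = DerivativeEngine(SystemModel(np.zeros((1, 1))), ms, basis,
                               variant="nonlinear")
        phi = np.zeros((len(basis), 1), complex)
        with pytest.raises(ValueError, match="zero-norm"):
            eng.apply(phi, np.zeros(1, complex), np.zeros(ms.n_modes, complex))

    def test_memory_stays_zero_for_unpopulated_site(self, bath):
        """xi_n has no drift source while site n carries no amplitude."""
        cfg = RunConfig(n_sites=3, coupling=0.0, variant="nonlinear", k_max=2,
                        dt=2.0, t_max=50.0, start_site=0)
        res = integrate(cfg, 2)
        ms = cfg.build_modeset()
        site2_modes = ms.modes_of_sites([2])
        np.testing.assert_allclose(res.memory[site2_modes], 0.0, atol=1e-14)
        site0_modes = ms.modes_of_sites([0])
        assert np.all(np.abs(res.memory[site0_modes]) > 0)

    def test_ensemble_average_matches_linear_equation(self, bath):
        """Girsanov equivalence: both unravelings give the same density
        matrix within combined statistical error (dimer, 600 pairs)."""
        kw = dict(n_sites=2, coupling=50.0, k_max=4, dt=2.0, t_max=100.0,
                  start_site=0)
        lin = run_ensemble(RunConfig(variant="linear", **kw), 600, 50)
        non = run_ensemble(RunConfig(variant="nonlinear", **kw), 600, 50)
        comb = np.sqrt(bootstrap_se(lin, 100, 1) ** 2 + bootstrap_se(non, 100, 1) ** 2)
        dev = np.abs(lin.populations - non.populations)
        assert np.max(dev / np.maximum(3 * comb, 1e-3)) < 1.0


class TestNormalizedEquation:
    def test_single_rk4_step_preserves_norm(self, bath):
        cfg = RunConfig(n_sites=2, coupling=50.0, variant="normalized", k_max=4,
                        dt=1.0, t_max=1.0)
        sys2 = cfg.build_system()
        ms = cfg.build_modeset()
        basis = triangular_basis(ms.n_modes, 4, ms.markovian)
        eng = DerivativeEngine(sys2, ms, basis, variant="normalized")
        noise = generate_noise(ms.modes, np.array([0.0, 0.5, 1.0]), 9, n_sites=2)
        phi = np.zeros((len(basis), 2), complex)
        phi[0] = [1.0, 0.0]
        xi = np.zeros(ms.n_modes, complex)
        zs = [np.conj(noise_at_all(noise, t)) for t in (0.0, 0.5, 1.0)]
        k1, m1 = eng.apply(phi, zs[0], xi)
        k2, m2 = eng.apply(phi + 0.5 * k1, zs[1], xi + 0.5 * m1)
        k3, m3 = eng.apply(phi + 0.5 * k2, zs[1], xi + 0.5 * m2)
        k4, _ = eng.apply(phi + k3, zs[2], xi + m3)
        phi1 = phi + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        assert abs(np.linalg.norm(phi1[0]) - 1.0) < 1e-8

    def test_rescaled_auxiliaries_bounded_unrescaled_divergent(self):
        """Single-mode hierarchy: with the k-dependent prefactor the
        auxiliary norms stay O(1) at every depth; without it they grow by
        orders of magnitude per level (|g/gamma| >> 1)."""
        bath = DrudeLorentzBath(50.0, 50.0, 295.0, None)
        capture = [np.array([k]) for k in range(11)]
        kw = dict(hamiltonian=np.zeros((1, 1)), baths=[bath], k_max=10, dt=2.0,
                  t_max=300.0, start_site=0, aux_capture=capture)
        rn = integrate(RunConfig(variant="normalized", **kw), 5)
        peak_norm = [max(rn.aux_capture[((0, k),)]) for k in range(1, 11)]
        assert max(peak_norm) < 10.0
        rl = integrate(RunConfig(variant="nonlinear", **kw), 5)
        peak_raw = [max(rl.aux_capture[((0, k),)]) for k in range(1, 11)]
        assert all(b > 50 * a for a, b in zip(peak_raw, peak_raw[1:]))

    def test_matches_post_normalized_nonlinear_trajectory(self, bath):
        """Change-of-variables equivalence on shared noise: the physical
        slice of the normalized equation equals the normalized physical
        slice of the nonlinear equation."""
        kw = dict(n_sites=2, coupling=50.0, k_max=6, dt=1.0, t_max=100.0,
                  start_site=0)
        rn = integrate(RunConfig(variant="normalized", **kw), 21)
        rl = integrate(RunConfig(variant="nonlinear", **kw), 21)
        assert np.max(np.abs(rn.populations() - rl.populations())) < 1e-5


class TestEnsembleObservables:
    def test_mirror_symmetric_chain_stays_symmetric(self, bath):
        ens = run_ensemble(
            RunConfig(n_sites=3, coupling=50.0, variant="normalized", k_max=4,
                      dt=2.0, t_max=100.0),
            n_traj=200, master_seed=3,
        )
        se = bootstrap_se(ens, 100, 0)
        dev = np.abs(ens.populations[:, 0] - ens.populations[:, 2])
        comb = np.sqrt(se[:, 0] ** 2 + se[:, 2] ** 2)
        assert np.max(dev / np.maximum(3 * comb, 1e-3)) < 1.0

    def test_density_matrix_hermitian_unit_trace_near_psd(self, bath):
        ens = run_ensemble(
            RunConfig(n_sites=2, coupling=50.0, variant="normalized", k_max=4,
                      dt=2.0, t_max=100.0, start_site=0),
            n_traj=150, master_seed=5,
        )
        np.testing.assert_allclose(
            np.trace(ens.rho, axis1=1, axis2=2).real, 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            ens.rho, np.conj(np.transpose(ens.rho, (0, 2, 1))), atol=1e-12
        )
        se = bootstrap_se(ens, 100, 0)
        eigs = np.linalg.eigvalsh(ens.rho)
        assert eigs.min() > -3 * se.max()

    def test_pure_dephasing_coherence_matches_closed_form(self, bath):
        """Stochastic dimer coherence vs the independent-boson decay."""
        cfg = RunConfig(hamiltonian=np.zeros((2, 2)), baths=[bath, None],
                        variant="normalized", k_max=8, dt=2.0, t_max=150.0,
                        initial_amplitudes=np.array([1.0, 1.0]) / np.sqrt(2))
        chunks = [run_ensemble(cfg, 150, 1 + 150 * c).rho[:, 0, 1] for c in range(4)]
        chunks = np.array(chunks)
        mean, se = chunks.mean(axis=0), chunks.std(axis=0, ddof=1) / 2.0
        oracle = 0.5 * dephasing_oracle(
            ModeSet.from_baths([bath]).modes, cfg.time_axis()
        )
        dev = np.abs(mean - oracle)
        assert np.max(dev / np.maximum(3 * np.abs(se), 2e-3)) < 1.0


class TestTerminator:
    def test_negligible_when_hierarchy_converged(self, bath):
        kw = dict(n_sites=2, coupling=50.0, variant="normalized", k_max=10,
                  dt=2.0, t_max=200.0, start_site=0)
        on = integrate(RunConfig(terminator=True, **kw), 3)
        off = integrate(RunConfig(terminator=False, **kw), 3)
        assert np.max(np.abs(on.populations() - off.populations())) < 1e-6

    def test_closure_scales_inversely_with_damping(self, bath):
        """The closure magnitude |g|/((k+1)gamma + ...) shrinks as the
        hierarchy depth (damping) grows at fixed g."""
        ms = ModeSet.from_baths([DrudeLorentzBath(50.0, 50.0, 295.0, None)])
        basis = triangular_basis(ms.n_modes, 3, ms.markovian)
        st = make_state(ms, basis, 1)
        for i, aux in enumerate(basis.members):
            st.wavefunctions[i, 0] = 1.0
        closures = apply_terminator(st, basis, ms, k_max=3)
        top = closures[(AuxIndex.from_dense([3]), 0)]
        shallow_basis = triangular_basis(ms.n_modes, 0, ms.markovian)
        st0 = make_state(ms, shallow_basis, 1)
        closure0 = apply_terminator(st0, shallow_basis, ms, k_max=0)[
            (AuxIndex.zero(), 0)
        ]
        assert abs(top[0]) < abs(closure0[0]) * 4  # (k+1)g/(4 gamma) vs g/gamma
        assert abs(top[0]) == pytest.approx(abs(4 * ms.g[0] / (4 * ms.gamma[0])), rel=1e-12)
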