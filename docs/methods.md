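# Methods

## Model

The package simulates a Frenkel exciton on an aggregate of `n_sites`
molecules.  The electronic Hamiltonian Ĥ_S (cm⁻¹) collects site energies
and electronic couplings; the built-in chain builder produces a uniform
tridiagonal chain with nearest-neighbor coupling V and molecular spacing
l₀, stored sparsely above 64 sites so mesoscale chains never densify.
Each site couples to its own harmonic environment exclusively through the
site projector L̂_n = |n⟩⟨n| (energetic, Holstein-type coupling; Peierls
coupling and shared baths are out of scope).

Environments are overdamped Drude–Lorentz oscillators with reorganization
energy λ (cm⁻¹), relaxation rate γ (cm⁻¹) and temperature T (K).  In the
high-temperature regime γ/k_BT < 1 (checked; a warning, not an error, is
raised outside it) the two-time correlation is the single exponential
α(t) = g e^{−γ|t|/ℏ}, g = 2λk_BT − iλγ.  Because Im α flips sign at t = 0,
the bare correlation is discontinuous there; a fast "Markovian" mode with
prefactor −i·Im[g] and rate γ_mark (default 500 cm⁻¹) is added so the total
correlation is continuous at the origin and relaxes back to the bare form
on the timescale ℏ/γ_mark.  γ_mark must merely be fast compared to all
physical dynamics; 1000 cm⁻¹ is appropriate when V reaches 250 cm⁻¹.

Units: energies in cm⁻¹, times in fs, with ℏ = 5308.837 cm⁻¹·fs and
k_B = 0.695035 cm⁻¹/K.  All equations divide energies by ℏ explicitly.

## Stochastic hierarchy

The non-Markovian quantum-state-diffusion unraveling writes the reduced
density matrix as an ensemble average of pure states driven by per-site
stationary complex Gaussian noise with E[z_t z*_s] = α(t−s) and
E[z_t z_s] = 0.  The functional-derivative term is unrolled into auxiliary
wave functions ψ^(k⃗) indexed by non-negative integer vectors over the
exponential bath modes.  Auxiliaries are scaled so that both hierarchy
couplings carry one power of 1/ℏ: the linear equation is

    ∂_t ψ^(k⃗) = (−iĤ_S/ℏ − k⃗·γ⃗/ℏ + Σ_s L̂_s z*_{s,t}/ℏ) ψ^(k⃗)
               + Σ_n k_n (g_n/ℏ) L̂_n ψ^(k⃗−e⃗_n)
               − Σ_n (1/ℏ) L̂_n† ψ^(k⃗+e⃗_n).

The non-linear equation applies the Girsanov drift: effective noise
z̃* = z* + Σ_n ξ_n with dξ_n/dt = (−γ_n* ξ_n + g_n* ⟨L̂_n†⟩_t)/ℏ, and the
up-flux operator becomes (L̂_n† − ⟨L̂_n†⟩_t), the expectation taken in the
normalized physical slice.  The normalized equation additionally rescales
auxiliary k⃗ by Π_n (γ_n/g_n)^{k_n} — turning the flux coefficients into
k_nγ_n/ℏ (down) and g_n/(γ_nℏ) (up), which keeps auxiliary magnitudes
bounded at every depth since |g/γ| ≫ 1 — and subtracts a scalar Γ_t from
every component, defined operationally as Γ_t = Re⟨ψ^(0)|∂_tψ^(0)⟩ so the
physical-norm derivative is exactly zero.  Whether Γ_t carries additional
flux-from-above pieces is a free choice of bookkeeping; defining it by the
zero-norm-derivative condition makes the normalized and post-normalized
non-linear trajectories coincide on shared noise, which the tests verify
numerically.

The basis uses triangular truncation: Σ_n k_n ≤ k_max over non-Markovian
modes.  Markovian modes are excluded from the depth budget, capped at
first order, and allowed only as pure e⃗_mark vectors (so a five-site chain
at k_max = 10 carries C(15,5) + 5 = 3008 auxiliaries; published counts for
this configuration are larger, ~9×10³, so the exact bookkeeping of
Markovian auxiliaries evidently differs between implementations — the
count implemented here is the one documented above and is used
consistently).  The optional terminator closes absent up-neighbors at the
depth boundary with ψ^(k⃗+e⃗_n) ≈ (k_n+1) g_n / ((k⃗+e⃗_n)·γ⃗) · L̂_n ψ^(k⃗),
valid when the auxiliary damping
dominates system frequencies; at k_max = 0 it reduces the hierarchy to
Markovian quantum state diffusion, which the tests compare against a
direct Lindblad integration including the surviving reorganization shift
−λ per site.

## Noise generation

Each site's process is generated by spectral filtering on a circulant
embedding: the Hermitian extension of the site's total decomposed
correlation is sampled on a power-of-two ring at the integrator step dt
(extended until the correlation has decayed at the ring midpoint), Fourier
transformed, and white circularly-symmetric Gaussian noise is filtered
through the square root of the spectrum.  This gives exactly zero
pseudo-correlation and the prescribed two-time correlation up to spectrum
clipping.  For the smooth (Markovian-corrected) correlation the circulant
spectrum is non-negative to rounding; for the bare discontinuous
correlation it acquires percent-level negative weight, which is clipped
with a warning (an error above 2% of the spectral maximum).  The lag-0
imaginary part is the midpoint of the sgn(t) jump, i.e. zero.

Per-site streams come from `SeedSequence(seed, spawn_key=(site,))`:
bit-reproducible, independent across sites, and stable under adding sites,
which is what makes shared-noise HOPS/adHOPS pairing and ensemble pairing
across chain lengths exact.  Noise between grid points is linearly
interpolated (needed at Runge–Kutta half-steps).

## Integration

Fixed-step classical RK4 with dt = 2 fs by default for the reference
parameter regime; the frozen-noise-path self-convergence test shows
fourth-order behavior (halving dt changes dimer populations by ~2×10⁻⁷).
After each step of the normalized/adaptive variants the whole hierarchy is
divided by the physical norm — a projection back onto the constraint
manifold the continuous equation preserves exactly, keeping the stored
norm at 1 to rounding.  Non-finite amplitudes abort with a diagnostic
(linear-variant trajectories, whose norms can genuinely diverge, are
flagged and excluded from the ensemble instead).

Ensembles run serially with trajectory i seeded master_seed + i, so
results are independent of any execution layout.  The density matrix is
the plain average of normalized projectors (normalized/non-linear
variants) or the norm-weighted average Σψψ†/Σ‖ψ‖² (linear).  Statistical
error is reported as a seeded bootstrap (200 resamples) over trajectories,
with a delta-method fallback when per-trajectory series are too large to
keep.

## Adaptive basis construction

Once per step, before the step, a reduced auxiliary/state basis is built
from the current state.  The candidate pool is the one-step neighborhood
of the current basis (hierarchy connectivity is nearest-neighbor; new
sites are reachable only through Ĥ_S off-diagonals).  For each candidate
slot the exclusion cost is the exact squared Euclidean norm of the
derivative the slot would receive from the current amplitude-carrying
members — a tight upper bound on any sub-selection of its sources.  For a
currently occupied member the cost adds the member's own dynamics and its
out-fluxes into retained slots.  Candidates are sorted by ascending cost
(ties broken by graded-lexicographic index, so runs are reproducible) and
the largest prefix whose cumulative cost fits the budget is excluded; the
budget δ² is split equally in quadrature, δ_aux² = δ_state² = δ²/2,
exposed as a configuration knob.  The physical wave function and any site
with physical amplitude above 10⁻¹² are never dropped.  δ = 0
special-cases to the full triangular basis, making adHOPS collapse onto
HOPS bit-for-bit.

The defining property — ‖D_full(ψ embedded) − D_adaptive(ψ)‖₂ ≤ δ at every
step, excluding the higher-order effect of Γ_t — is verified directly on a
three-site chain at δ = 10⁻⁴.  The derivative-error bound does not control
the instantaneous amplitude discarded when an occupied member is dropped;
like the underlying method, δ is a convergence parameter and the
convergence tests (population error falling monotonically over
δ ∈ {10⁻¹, 10⁻², 10⁻³}) are the operational check.

## What the synthetic systems do and do not cover

All test systems are uniform linear chains (or dimers) at the reference
point λ = γ = 50 cm⁻¹, T = 295 K, V = 10–100 cm⁻¹, excited on the middle
site — the intermediate-coupling regime where perturbative methods fail.
Real aggregates add static energetic disorder, structured spectral
densities with underdamped intramolecular modes, finite-range dipolar
couplings and correlated environments; none of these are represented, so
passing tests demonstrate correctness of the equations and the adaptive
truncation logic, not transferability of any particular diffusion constant
to a material.  Low-temperature (Matsubara) corrections are likewise out
of scope: outside γ/k_BT < 1 the single-exponential decomposition itself
is inaccurate.

## Problem sizes used in tests and the acceptance script

Chosen as desk-scale versions of the study conditions: shared-noise
adaptive-error and compression runs use the five-site chain at k_max = 10
with 500 paired / 100 single trajectories over 200/600 fs windows; the
size-invariance scan uses chains of 5–30 sites at k_max = 4, 30
trajectories each over 200 fs; oracle comparisons use dimers with 10³
trajectories; the diffusion demonstration uses a 25-site chain, V = 100
cm⁻¹, 40 adaptive trajectories over 300 fs.  The windows are long enough
to cover the initial transfer dynamics and the adaptive basis's growth
plateau; ensemble sizes put bootstrap errors at the few-×10⁻³ level, well
below the effects being measured.  The diffusion coefficient is reported
in the MSD = 2Dt convention (1-D) with the fit window defaulting to the
second half of the series; it is a demonstration quantity — its absolute
value depends on the fit window and convention and is checked only for
being positive, finite, and diffusive (low fit residual).

## Known limitations

- Site-projection coupling operators only; no Peierls/off-diagonal
  coupling, no shared or spatially correlated baths.
- One Drude–Lorentz oscillator (plus its Markovian correction) per site;
  no multi-exponential or underdamped modes, no complex-γ terminator.
- Fixed-step integration; no adaptive time stepping or checkpointing.
- The linear-variant ensemble converges slowly (heavy-tailed norm
  weights); it exists as a reference and for the Girsanov-equivalence
  test, not for production runs.
- Dropping an occupied basis member changes the state discontinuously;
  only the derivative error is bounded by δ (see above).
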