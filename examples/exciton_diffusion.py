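"""Exciton diffusion on a long chain with size-invariant adaptive cost.

Starts an excitation on the middle pigment of a 25-molecule chain
(V = 100 cm^-1), averages 30 adaptive trajectories, and extracts the
diffusion coefficient from a linear fit to the mean-squared displacement
(MSD = 2 D t in one dimension, distances in molecular spacings l_0).
"""

from adhops import RunConfig, diffusion_coefficient, msd, run_ensemble

cfg = RunConfig(n_sites=25, coupling=100.0, variant="adaptive", k_max=4,
                delta=1e-3, dt=2.0, t_max=300.0)
ens = run_ensemble(cfg, n_traj=30, master_seed=7)

series = msd(ens.populations, start_site=12)
fit = diffusion_coefficient(ens.t, series)

print(" t/fs    MSD/l_0^2")
for i in range(0, len(ens.t), 25):
    print(f"{ens.t[i]:6.0f}   {series[i]:8.3f}")
print(f"\nD = {fit.D:.4f} l_0^2/fs  (fit window {fit.window[0]:.0f}-"
      f"{fit.window[1]:.0f} fs, relative residual {fit.residual:.3f})")
print(f"with l_0 = 10 A: D = {fit.D_cm2_per_s(1e-7):.3e} cm^2/s")
print(f"mean adaptive basis: {ens.mean_aux_size().mean():.0f} auxiliaries, "
      f"{ens.mean_state_size().mean():.1f} of 25 sites")
print("The basis size tracks the exciton's footprint, not the chain length;"
      "\nthe same run on a 1000-molecule chain costs essentially the same.")
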