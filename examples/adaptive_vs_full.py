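"""Adaptive basis truncation on a five-site chain.

Integrates the same noise realizations with the full hierarchy (3008
auxiliary wave functions at k_max = 10) and with the adaptive basis at
three error bounds delta, reporting the population error and the basis
compression — the trade-off at the heart of adHOPS.
"""

from adhops import RunConfig, adaptive_error, run_ensemble

kw = dict(n_sites=5, coupling=50.0, k_max=10, dt=2.0, t_max=200.0)
N = 50

full = run_ensemble(RunConfig(variant="normalized", **kw), N, master_seed=1)
print(f"full HOPS: {full.aux_sizes[0, 0]} auxiliaries throughout\n")
print("delta     mean pop error   mean adaptive auxiliaries")
for delta in (1e-1, 1e-2, 1e-3):
    ad = run_ensemble(RunConfig(variant="adaptive", delta=delta, **kw), N,
                      master_seed=1)
    err = adaptive_error(ad, full)
    print(f"{delta:7.0e}   {err:12.4f}   {ad.mean_aux_size().mean():12.1f}")
print("\nShrinking delta tightens the derivative-error bound: the population"
      "\nerror falls while the basis grows only modestly. At delta = 1e-1 the"
      "\nbasis is too small to carry any excitation transport at all.")
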