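"""Locality inside the hierarchy of a single trajectory.

On a weakly-coupled five-site chain (V = 10 cm^-1) the auxiliary wave
functions attached to a site's thermal environment acquire norm only while
that site is populated — the mechanism the adaptive basis exploits.  This
script captures the first-order auxiliaries of the two sites flanking the
initially excited middle site (two modes per site, slow mode first) along
one trajectory and reports their correlation with the site populations.
(The start site itself anti-correlates with its auxiliaries early on: its
population falls from one while its hierarchy builds from zero.)
"""

import numpy as np

from adhops import RunConfig, integrate

cfg = RunConfig(n_sites=5, coupling=10.0, variant="normalized", k_max=10,
                dt=2.0, t_max=1000.0,
                aux_capture=[[0, 0, 1, 0, 0, 0, 0, 0, 0, 0],   # site 1 slow mode
                             [0, 0, 0, 0, 0, 0, 1, 0, 0, 0]])  # site 3 slow mode
res = integrate(cfg, 17)
pops = res.populations()

print("auxiliary        tracks site   correlation")
for key, series in res.aux_capture.items():
    mode = key[0][0]
    site = mode // 2
    corr = np.corrcoef(series, pops[:, site])[0, 1]
    print(f"e_{mode:<14d} {site:^11d}   {corr:.3f}")
print("\nCorrelations near 1 mean hierarchy amplitude clusters on the"
      "\nauxiliaries of currently-populated sites, so a reduced basis that"
      "\nfollows the exciton loses almost nothing.")
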