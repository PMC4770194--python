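"""Victor-Purpura transmission fidelity between connected units.

The distance D between two spike trains is the minimal edit cost
(insert/delete at cost 1, shift at cost q per unit time); normalized,
D_v = D/(n1+n2) in [0,1], and fidelity is lambda = 1 - D_v. Coarse cost
scales (1/q of 80-200 ms) probe rate-code similarity; fine scales (2-20 ms)
probe precise spike timing.
"""
import numpy as np

import netfidelity as nf

rng = np.random.default_rng(0)
source = np.sort(rng.uniform(0, 60, 150))

for jitter_ms, label in ((0.0, "perfect relay"), (5.0, "5 ms jitter")):
    target = np.sort(source + rng.normal(0, jitter_ms * 1e-3, source.size))
    prof = nf.fidelity_sweep(source, target)
    print(f"{label}:")
    for qinv, lam in zip(prof.qinv_ms, prof.lam):
        print(f"  1/q = {qinv:5.0f} ms   lambda = {lam:.3f}")
    print(f"  rate-band mean {prof.rate_band_mean:.3f}   "
          f"temporal-band mean {prof.temporal_band_mean:.3f}")
# Jitter leaves rate-scale fidelity nearly intact but erodes the fine
# temporal scales - the signature of a rate code surviving noisy synapses.
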