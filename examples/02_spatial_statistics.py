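"""Classify the spatial distribution of events inside an irregular cell mask.

Compares uniform (CSR), clustered (Thomas) and dispersed (hardcore) point
patterns on a neuron-like mask against Monte-Carlo envelopes of Ripley's
L(r) built on the very same mask.
"""

import numpy as np

from exospot import spatial, synth

mask = synth.neuron_like_mask((256, 256), pixel_size=0.1, seed=3)
r = spatial.default_r_grid(mask)
n = 100

# one envelope serves every pattern with this mask and point count
med, mad = spatial.mc_envelope(mask, n, r, n_sims=2000, seed=7)

print(f"mask area: {mask.area_um2:.1f} um^2, "
      f"{n} events, r up to {r[-1]:.1f} um\n")
for mode in ("uniform", "thomas_clustered", "hardcore_dispersed"):
    # the slim neurites keep the mask small, so the hardcore distance must
    # stay modest for 100 points to fit
    pat = synth.simulate_point_pattern(mask, mode, n, seed=11,
                                       min_distance=0.45)
    L = spatial.ripley_L(pat, r)
    z, usable = spatial.spatial_zscore(L, med, mad)
    labels = spatial.classify_z(z[usable])
    verdict = ("clustered" if (z[usable] > 2).any()
               else "dispersed" if (z[usable] < -2).any() else "uniform")
    print(f"{mode:20s} max z = {z[usable].max():6.2f}  "
          f"min z = {z[usable].min():6.2f}  -> {verdict}")

print()
print("z(r) = (L_obs - median_sim) / (1.4826 * MAD_sim); |z| > 2 at any")
print("radius departs from complete spatial randomness at roughly the")
print("two-sigma level. The envelope is rebuilt per cell, so irregular")
print("shapes need no analytic edge correction.")
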