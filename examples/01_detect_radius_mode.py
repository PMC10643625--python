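"""Detect a continuous radius mode in simulated NPC-like rings.

Simulates 40 ring particles whose radius varies uniformly between 40 and
60 nm, runs the full heterogeneity pipeline (registration -> MDS ->
Isomap gate -> PCA), and compares the recovered 1-D latent coordinate to
the ground-truth radius.
"""

import numpy as np
from scipy.stats import spearmanr

from chd import CHDConfig, NPCSimConfig, run_chd, simulate_npc

ps, truth = simulate_npc(
    NPCSimConfig(n_particles=40, radius_dist=("uniform", 40.0, 60.0), seed=2)
)
res = run_chd(ps, CHDConfig(scale=5.0, fuse=False, seed=2))

rho = spearmanr(res.latent.coordinate, truth["radius"]).statistic
print(f"particles:                 {len(ps)}")
print(f"MDS raw stress (D=30):     {res.provenance['mds_stress']:.2e}")
print(f"isomap applied:            {res.used_isomap}")
print(f"PC1 variance explained:    {100 * res.variance_explained_pc1:.1f}%")
print(f"spearman(latent, radius):  {rho:+.3f}")
print()
print("A |spearman| close to 1 means the latent coordinate orders the")
print("particles by their true radius, found without any structural model;")
print("a dominant PC1 variance share signals a single strong mode.")
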