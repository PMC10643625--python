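"""Fuse particles per latent bin and compare blob sharpness.

Heterogeneous particles fused together produce smeared ('elongated')
binding-site blobs; fusing each latent-space bin separately keeps
structurally similar particles together and sharpens the blobs.
"""

import numpy as np
from sklearn.cluster import KMeans

from chd import (
    CHDConfig,
    NPCSimConfig,
    assign_bins,
    fuse_per_bin,
    jrmpc_fuse,
    run_chd,
    simulate_npc,
)

ps, truth = simulate_npc(
    NPCSimConfig(n_particles=40, radius_dist=("uniform", 30.0, 70.0), seed=5)
)
res = run_chd(ps, CHDConfig(scale=5.0, fuse=False, seed=5))
bins = assign_bins(res.latent, n_bins=4, strategy="uniform", min_particles=5)
recs = fuse_per_bin(ps, bins, n_components=8, rng_seed=0)
full = jrmpc_fuse(list(ps), n_components=8, rng_seed=0)


def site_spread(coords):
    km = KMeans(8, n_init=10, random_state=0).fit(coords)
    d = np.linalg.norm(coords - km.cluster_centers_[km.labels_], axis=1)
    return float(np.sqrt((d**2).mean()))


print(f"whole-set fusion   per-site RMS spread: {site_spread(full.fused_coords):6.2f} nm")
for rec in recs:
    members = bins.members(rec.bin_label)
    print(
        f"bin {rec.bin_label} ({members.size:2d} particles)  "
        f"per-site RMS spread: {site_spread(rec.fused_coords):6.2f} nm"
    )
print()
print("Per-bin spreads below the whole-set spread show that latent binning")
print("removes the radial smearing caused by the radius heterogeneity.")
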