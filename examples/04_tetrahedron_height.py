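"""3D example: continuous height variation of DNA-origami tetrahedra.

Simulates tetrahedra (100 nm base edge) with height varying uniformly over
67.5-112.5 nm, fuses groups of similar height, and estimates each group's
height from the bimodal axial projection (base plate vs tip).
"""

import numpy as np

from chd import (
    Particle,
    TetraSimConfig,
    estimate_height,
    jrmpc_fuse,
    simulate_tetrahedron,
)

ps, truth = simulate_tetrahedron(TetraSimConfig(n_particles=24, seed=4))
order = np.argsort(truth["height"].to_numpy())

for name, idx in (("short third", order[:8]), ("tall third", order[-8:])):
    rec = jrmpc_fuse([ps[int(i)] for i in idx], n_components=4, rng_seed=0)
    est = estimate_height(Particle(rec.fused_coords, id=name), axis_align="auto")
    true = truth["height"].to_numpy()[idx].mean()
    print(
        f"{name}: estimated height {est.height:6.1f} nm "
        f"(ground-truth mean {true:6.1f} nm, flagged={est.flagged})"
    )
print()
print("The height is read off as the distance between the two modes of the")
print("fused localizations projected on the symmetry axis; agreement with the")
print("ground truth validates the axial estimator on anisotropic 3D data.")
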