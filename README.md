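# chd — continuous heterogeneity detection for SMLM particles

Single-molecule localization microscopy (SMLM) resolves individual copies
("particles") of macromolecular structures — nuclear pore complexes, DNA
origami — as point clouds of fluorophore localizations. Averaging many
particles into a *superparticle* boosts resolution, but only if the
particles are structurally identical. Real datasets carry **continuous
structural heterogeneity**: a nuclear pore's ring radius, an origami
tetrahedron's height. Averaging across it blurs exactly the features one
wants to see.

`chd` orders particles along that hidden structural axis without any
template or model, using nothing but pairwise point-cloud dissimilarities,
then fuses particles per bin of the recovered coordinate so each
reconstruction averages only look-alikes. It is a library for Python use
(see `examples/`), with a thin `chd` command-line wrapper.

## Method

1. **All-to-all registration.** Every pair of particles (A, B) is rigidly
   aligned by maximizing the Gaussian-mixture overlap

   C(A, B) = (1/|A||B|) Σ_{a∈A} Σ_{b∈B} exp(−‖a−b‖² / 4σ²),

   a Bhattacharyya-type kernel cost normalized by localization counts,
   from multiple initial poses. The kernel width σ is chosen by a scale
   sweep over random particle groups. The optimal pair costs, subtracted
   from their maximum, form an N×N dissimilarity matrix d.
2. **MDS embedding.** Coordinates x_i in a D = 30 dimensional abstract
   space are found by SMACOF minimization of the raw stress
   S = Σ_{i<j} (d_ij − ‖x_i − x_j‖)².
3. **Isomap unrolling (gated).** If the variance profile of the embedding
   shows a dominant curved manifold — (v₁−v₂) and (v₂−v₃) both above half
   the mean variance per axis — Euclidean distances are replaced by
   k-nearest-neighbor graph geodesics (k = 4) and re-embedded.
4. **PCA latent space.** Projection on the leading principal axis gives a
   1-D latent coordinate; its variance-explained share measures how
   dominant the structural mode is.
5. **Binned fusion.** The latent axis is split into bins (uniform width, or
   half the fitted Gaussian sd for bell-shaped distributions) and each bin
   is fused with JRMPC — joint EM over one rigid transform per particle
   plus a shared Gaussian-mixture scene with a uniform outlier component.
6. **Validation & QC.** Model-based estimators (ring radius, tetrahedron
   height, ring ellipticity), Fourier-ring-correlation-based spectral SNR
   curves per bin (SSNR = 2·FRC/(1−FRC)), and flagging of the extreme 1%
   of the latent distribution as outlier candidates.

Simulators for heterogeneous NPC-like rings (8 × 4 binding sites, Bernoulli
degree of labeling, Poisson localization counts, Gaussian localization
noise) and DNA-origami tetrahedra ship with ground-truth tables for
validation.

## Worked example

```sh
python examples/01_detect_radius_mode.py
```

```
particles:                 40
MDS raw stress (D=30):     4.92e-03
isomap applied:            False
PC1 variance explained:    99.4%
spearman(latent, radius):  +0.996
```

Forty simulated rings with radius uniform over 40–60 nm: the latent
coordinate reproduces the ground-truth radius ordering almost perfectly
(|ρ| = 0.996) and the first principal axis carries 99.4% of the embedding
variance — a single dominant structural mode, discovered without telling
the pipeline that "radius" exists. (Here the Isomap gate decides the MDS
cloud is already flat enough and applies PCA directly.) `examples/02_binned_fusion.py` shows the
blob sharpening from per-bin fusion, `03_ssnr_and_outliers.py` the SSNR
quality curves and outlier rule, and `04_tetrahedron_height.py` the 3D
tetrahedron height mode.

The same pipeline from the shell:

```sh
chd simulate npc --n 100 --radius 30 70 --seed 1 --out particles.csv
chd run --particles particles.csv --scale auto --out-dir results/
```

## Layout

- `src/chd/core.py` — particle/transform types, table I/O, rendering
- `src/chd/registration.py` — kernel cost, pairwise registration, scale
  sweep, dissimilarity matrix
- `src/chd/embedding.py` — SMACOF MDS, Isomap, PCA latent space
- `src/chd/fusion.py` — latent binning, JRMPC fusion
- `src/chd/quality.py` — shape estimators, SSNR, outlier detection
- `src/chd/simulate.py` — NPC ring and tetrahedron generators
- `src/chd/pipeline.py` — orchestration and simulation experiments
- `docs/methods.md` — model assumptions, parameter choices, limitations
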