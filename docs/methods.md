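# Methods

## Model and assumptions

The pipeline treats each SMLM particle as an unordered point cloud of
localization coordinates (nm). It assumes particles are independent rigid
copies of structures drawn from a family varying continuously in one or a
few shape parameters; it does not assume what those parameters are, any
symmetry, or a template. Dissimilarity between two particles is measured
after rigid alignment only (rotation + translation, no reflection — SMLM
particles of one dataset are not mirror-ambiguous), so the latent
coordinate can only reflect variation that survives rigid alignment.

### Pairwise kernel cost

Each cloud is an equal-weight isotropic Gaussian mixture of width `scale`
(one component per localization). The alignment score is

    C(A,B) = (1/|A||B|) * sum_{a,b} exp(-||a-b||^2 / (4 scale^2)),

the mean cross-pair kernel value: symmetric, bounded in (0, 1], invariant
to a common rigid motion, and — because of the 1/|A||B| factor — invariant
to duplicating localizations, which makes the dissimilarity matrix
insensitive to per-particle localization counts. Dividing by the product of
counts (rather than the sum) turns the double sum into an average, giving
the bound at 1; this is the package's fixed convention.

Registration maximizes C over SE(2)/SE(3). In 2D the rotation-only cost
along the centroid-aligned clouds is a function of precomputable inner
products, so each of the 6 equally spaced initial poses is refined by a
bounded 1-D search in its angular sector, followed by a joint
rotation+translation ascent from the best pose. In 3D the 12 proper
rotations of the tetrahedral group serve as a near-uniform deterministic
pose sample, each refined by manifold gradient ascent (left-multiplicative
rotation updates, backtracking line search). Pose search runs on an
even-stride subsample of at most 150 points per cloud for speed; the
reported cost is always evaluated on the full clouds at the final
transform. Pairs whose optimization produces no finite cost are flagged
and assigned maximal dissimilarity rather than aborting the O(N²) job.

### Scale selection

The raw bounded cost grows monotonically toward 1 as the kernel widens, so
optimal costs obtained at different scales cannot be compared directly.
The sweep therefore registers all pairs within ten random groups (ten
particles each) at every candidate scale (default geometric grid
1–50 nm), and scores each resulting *alignment* with the cost at one
common evaluation kernel, fixed at 3× the median nearest-neighbor distance
of the sampled particles — the NN distance reflects within-blob sampling
density, and a few multiples of it approximate the localization-precision
scale at which alignment quality matters. The score peaks at an interior
scale: undersized kernels leave the optimizer in noise optima
("overfitting on each localization"), oversized kernels blur neighboring
binding sites together and lose pose sensitivity. The candidate with the
best mean score over groups wins.

### Dissimilarity, MDS, Isomap, PCA

Dissimilarities are `d_ij = max_pair_cost − cost_ij` (zero diagonal, best
pair exactly 0). MDS uses SMACOF majorization (Guttman transform, unit
weights) of the raw summed stress `S = Σ_{i<j} (d_ij − ||x_i − x_j||)²`,
initialized from classical Torgerson scaling plus one random restart;
stopping at relative stress decrease < 1e-9 or 2000 iterations. Majorization
guarantees monotone non-increasing stress, which the tests assert
per-iteration. D = 30 dimensions is the working default. Stress is reported
raw (unnormalized): note that cost-derived dissimilarity matrices are not
exactly Euclidean (their double-centered Gram matrices carry negative
eigenvalues), so the attainable stress floor is set by that non-Euclidean
part, not by the optimizer — on simulated ring data the floor is ~1e-3 and
is unchanged by extra iterations or extra dimensions.

Isomap re-embeds graph geodesics: k-nearest-neighbor graph (k = 4 default,
4–12 sensible) on Euclidean distances in MDS space, union symmetrization
(an edge exists if either endpoint lists the other), Dijkstra all-pairs
shortest paths, re-embedding at the same dimensionality. A disconnected
graph raises an error naming the component count — it is never silently
bridged; the pipeline's `auto` mode then falls back to PCA on the MDS
embedding, since a disconnected graph means the manifold assumption fails
at this k. The applicability gate — run Isomap only when (v1−v2) and
(v2−v3) both strictly exceed half the mean variance explained per axis —
implements the two-difference reading of "successive differences on the
first three axes"; an isotropic embedding fails it and goes straight to
PCA.

PCA mean-centers the embedding and projects on the top axes; each axis's
sign is fixed so the score skewness is nonnegative (ties: first particle
nonnegative) to make runs and tests reproducible, since the latent sign is
inherently arbitrary.

### Binning and JRMPC fusion

Uniform binning spans [min, max] of the latent coordinate with equal
widths; Gaussian binning fits a Gaussian by maximum likelihood on the raw
latent values (equivalent to and cleaner than fitting the histogram) and
uses bins of width sd/2 centered on the mean, clamping stragglers into the
edge bins. Bins under `min_particles` (default 10) are flagged but still
fused. Fusion is JRMPC: EM over one rigid transform per particle plus a
shared scene mixture of isotropic Gaussians (default component count
⌈median localizations per particle / 4⌉, capped at 64) and a uniform
outlier component (weight 0.05 over the data bounding box). Transform
updates are weighted Kabsch solutions toward per-point virtual targets;
center/variance updates are closed-form; the observed-data log-likelihood
is non-decreasing and is returned for inspection. Poses are initialized by
registering every particle onto the first one pairwise — identity
initialization, though cheaper, reliably hits poor local optima once
particle orientations span the full rotation group. Variances are floored
at 1e-8 nm² for numerical safety.

### Shape estimators and quality measures

* Ring radius: center by the mean localization, mean of polar radii; the
  SEM is FWHM/√n with FWHM = 2√(2 ln 2)·sd computed analytically from the
  radial sd, avoiding histogram bin-width sensitivity. Note the estimator
  carries the Rician bias ≈ σ²/(2R) under localization noise σ.
* Tetrahedron height: project pooled localizations on the symmetry axis
  and fit a two-component Gaussian mixture; height = |μ₂ − μ₁|. The axis
  is found automatically as the principal axis with the strongest
  bimodality (best 2-mixture separation), oriented with the lighter mode
  (tip) positive; a rotation or axis vector can be supplied instead. Fits
  with separation < 2 component sds are flagged as effectively unimodal
  (below that a two-Gaussian mixture has a single mode).
* Ring ellipticity: k-means (k = 8, best of 10 restarts) for blob centers,
  least-squares ellipse fit, minor/major ratio.
* SSNR: random half-split of the bin, independent JRMPC fusion of each
  half, rigid alignment of half 2 onto half 1, then a per-particle random
  rotation by an integer multiple of 2π/8 (configurable symmetry order;
  1 = off) to scramble binding-site occupancy hotspots while preserving
  8-fold-symmetric signal. Both halves are rendered on a common grid and
  SSNR(q) = 2·FRC(q)/(1 − FRC(q)), capped at 1e6. No single-number
  resolution criterion is derived beyond where SSNR crosses 1.
* Outliers: the extreme `fraction` (default 1%) of the latent
  distribution, split evenly over both tails, strict quantile rule;
  invariant under affine latent rescaling.

### Synthetic data

The ring generator emulates Nup96-like NPC labeling: 8 corners × 4 binding
sites collapsed onto the corner positions of an ellipse
(x = r cos θ, y = e·r sin θ), per-site Bernoulli activation with
probability DOL, per-active-site localization counts Poisson(λ = 10)
conditioned ≥ 1, isotropic Gaussian localization noise (default 5 nm),
uniform random in-plane rotation and ±10 nm picking jitter; particles with
zero active sites are redrawn. The tetrahedron generator places an
equilateral 100 nm base triangle plus a tip at height h (default uniform
67.5–112.5 nm: centered on 90 nm with a 45 nm span), uses the same
labeling model with anisotropic lab-frame noise (5 nm lateral, 15 nm
axial) and uniform random 3D rotations. λ = 10, the 5/15 nm precisions and
the ±10 nm jitter are typical SMLM operating values chosen once for all
studies. All randomness derives from the single config seed;
identical configs are bit-reproducible.

What the simulators do **not** model: blinking kinetics and repeated
on-switching, drift, multi-emitter fitting artifacts, false-positive
background localizations, and segmentation errors beyond translation
jitter. Passing tests on this data therefore demonstrates that the
pipeline recovers continuous geometric modes under idealized labeling and
noise statistics; real datasets add confounders (notably background and
DOL far below 100%) that degrade the latent space as the DOL study shows.

## Problem sizes

Simulation studies run at desk scale: 60 particles per condition for the
single-mode, DOL and two-mode studies in the test suite (5 seeds where a
median is reported), and 100 particles for the headline acceptance run —
the package's standard working sizes for validation, with ~320
localizations per particle at full labeling. The O(N²) registration stage
dominates the cost (~20 ms per pair at these sizes).

## Known limitations

* The dissimilarity is a single global measure; modes it is weakly
  sensitive to (e.g. ellipticity next to a strong radius mode) appear only
  on later principal axes with small variance share.
* Cost-derived dissimilarities are non-Euclidean; the raw-stress floor of
  the MDS embedding is data-dependent and nonzero.
* The Isomap gate is a heuristic; k is not auto-selected beyond the
  exposed 4–12 range.
* Latent-extreme outlier flagging finds structures at the ends of the
  dominant mode; contaminant particles whose dissimilarity pattern is
  orthogonal to that mode can escape the rule.
* No GPU or multi-process batching; pairs are independent and the
  registration loop is trivially parallelizable in principle.
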