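# Methods

`hybridseg` implements a three-stage hybrid pipeline for volumetric
segmentation of solid lesions and organs in 3D scans — the motivating case is
the stented abdominal aortic aneurysm on post-EVAR contrast CT, where the
bright stent+lumen sits inside a hypodense thrombus whose outer boundary is
weakly contrasted and often degraded by artifacts.  The package also contains
the synthetic phantom generator used to exercise the pipeline end-to-end and
the full evaluation-metric suite.

## 1. Variational initial segmentation

One volume per study is segmented interactively from a handful of seed
points.  The model is a convex relaxed two-phase region energy over a
relaxation u ∈ [0, 1] per voxel:

    E(u) = ∫ g |∇u|  +  λ ∫ [ u (I − c_in)² + (1 − u)(I − c_out)² ]  +  μ ∫ u d(x)

**Edge indicator.**  g = 1 / (1 + β |∇(G_σ ∗ Ĩ)|²), where Ĩ is the image
normalized by its local mean and standard deviation (7³ window, with an
absolute floor of 0.05 + 0.1·global-std in the denominator so flat noisy
regions are not amplified).  Local contrast normalization is what makes weak
boundaries produce deep minima of g; it can be disabled
(`enhance_contrast=False`).  Defaults σ = 1 voxel, β = 100.

**Region term.**  c_in is the mean intensity in a 1-voxel neighbourhood of
the inside markers (kept tight so thin structures do not leak neighbouring
intensities into the seed statistics); c_out from the outside markers or the
complement.  The
raw term (I − c_in)² − (I − c_out)² is quadratic in the (possibly tiny)
contrast, so the solver normalizes the region weight once by the initial
marker contrast, λ_eff = λ / (c_in − c_out)²; λ then means the same thing at
contrast 0.5 and at contrast 0.05.  The means are re-estimated from the
relaxation every 10 outer iterations (u-weighted means, which can only lower
the energy).  Default λ = 1; the phantom benchmark uses λ = 0.5, which is
more robust at noise levels comparable to the boundary contrast.

**Location term.**  d(x) is the Euclidean distance transform from the inside
markers in mm, normalized by its 95th percentile and clipped to [0, 1]; an
intensity-weighted geodesic variant is available.  μ (default 0.5) shrinks
the solution toward the seeds; raising it never grows the thresholded mask.

**Solver.**  Projected gradient descent on the ε-smoothed total variation
(ε = 10⁻³) with monotone Armijo backtracking.  A dual/primal-dual scheme
converges faster in iterations, but its primal energy is not monotone
per-iteration; backtracked descent guarantees a non-increasing energy trace
on every run, which we treat as a contract (it is asserted in the tests).
Stopping: max |Δu| < tol (default 10⁻⁴) or an energy plateau over a 10-
iteration block; hitting `max_iters` (default 500) flags `converged=False`
on the output instead of raising.  Thresholding at θ = 0.5 recovers the
mask, ties to foreground.  Anisotropic spacing enters through 1/h-scaled
finite differences; arrays are (z, y, x), 0-based.

Multi-class segmentation (thrombus = 1, stent+lumen = 2) runs one solve per
class and resolves overlaps by the larger u, exact ties to the lower label.

## 2. Registration-based propagation

Each further volume receives an *estimate* by registering the segmented
reference volume onto it and resampling the saved mask through the recovered
transform (nearest-neighbour for labels, linear for images, out-of-field →
background).  The registration is classical and deterministic: NCC metric,
dense sampling, 3-level multiresolution, regular-step gradient descent, one
affine stage initialized by aligning structural centres of mass (weights
|I − median(I)|, so both hyper- and hypodense structures count and the flat
background does not).  A divergence guard scores {identity, moments shift,
optimized affine} by NCC on σ=2-smoothed volumes and keeps the most
expressive candidate within 0.02 of the best score — resampling blur biases
raw NCC toward candidates that move less, so a plain argmax would reject
good registrations, while a genuinely diverged affine scores far below the
moments shift and is discarded.  An optional demons stage
(`mode="affine+deformable"`) refines the affine result.  Transforms live in
physical mm, fixed ← moving.

The estimates are deliberately imperfect (on the benchmark cohort they
average ≈ 0.8 whole-lesion Dice): their role is to localize and roughly
shape the target for the refinement network, not to be the answer.

## 3. Refinement network and semi-supervised training

A compact 3D U-Net (3 resolution levels, two conv-instancenorm-LeakyReLU
blocks per level, average-pool down, factor-2 linear upsampling with exact
adjoint, softmax head; base width 16 ⇒ ≈ 355 k parameters) implemented
directly on numpy with explicit layer-wise backpropagation — convolutions
run as 27 offset GEMMs, everything is float32 and bit-deterministic given
the seed, and the backward passes are finite-difference checked in the test
suite.  Two input configurations:

* **hybrid** — the scan plus one one-hot channel per foreground class of the
  estimated segmentation;
* **standard** — the scan alone (the conventional baseline).

Loss is w_dice·softDice (mean over foreground classes) + w_ce·cross-entropy
(defaults 0.5/0.5), optimized with Adam (lr 10⁻³–2·10⁻³, batch 2 by gradient
accumulation).  Unlabelled volumes enter hybrid training with their
variationally refined estimates as *pseudo-labels*, the same loss scaled by
`pseudo_label_weight` (default 0.5; at 0 the pseudo examples are dropped
entirely, making the run identical to a supervised one).  The standard
baseline trains supervised on labelled volumes only.  Validation Dice picks
the best checkpoint; early stopping patience defaults to 15 epochs.
Augmentation is limited to seeded axis flips plus — in hybrid mode —
*estimate-channel dropout* (`estimate_dropout_p`, default 0.3): the estimate
channels of a training patch are zeroed at random so the network also learns
the image-only mapping instead of copying a possibly wrong estimate.
Augmentation is off in determinism tests.  Inference is sliding-window with half-patch stride and probability
averaging; volumes smaller than the patch run in one window, after padding
to the network stride (4).

## 4. Synthetic phantoms

The generator renders scenes with exact analytic ground truth:

* **aneurysm** — a circular lumen tube (radius r_l, the stent stays round)
  swept along a sinusoidally wobbling vertical centerline (amplitude, number
  of periods and phase all controllable) inside a coaxial thrombus tube
  whose cross-section is an area-preserving ellipse (axis ratio and
  orientation controllable) of outer radius r_t, optionally off-centre and
  optionally *fusiform* (`sac_length_mm`: the ring bulges over a sac and
  tapers to the bare lumen at both necks).  Intensities follow the
  contrast-CT ordering lumen 0.9 > background 0.4 > thrombus
  (= background − boundary_contrast).  The scene can additionally carry a
  spine-like bright column at a near-fixed posterior position (the shared
  landmark registration anchors on) and `n_distractors` clutter structures
  (bright vessel-like tubes and hypodense blobs that never touch the target);
* **tumour** — union of 3–7 overlapping random spheres, bright on smooth
  background;
* **organ** — a superellipsoid (exponent 2.5).

Degradations: additive Gaussian noise (σ in intensity units on [0, 1]),
smooth Gaussian-filtered background texture, and *boundary-contrast
dropout* — a random angular sector covering `dropout_fraction` of the outer
thrombus boundary where, within a shell of 2 voxels (capped at half the
local ring thickness, so dropout degrades the boundary rather than erasing
the region), the thrombus intensity is set equal to the background (a
controlled stand-in for contrast gaps and artifacts; at fraction 1 the whole
outer boundary disappears).  All randomness flows through `rng_seed`;
cohorts jitter chosen fields uniformly within ranges, each phantom getting a
derived seed.  Straight uniform tubes have closed-form volumes (π r² L,
preserved under the area-preserving ellipse) used as test oracles, and
voxelization error shrinks with spacing.

What the phantoms do **not** emulate: CT physics (beam hardening, streaks),
anatomical shape variability beyond radius/wobble/position jitter,
neighbouring organs, or intensity inhomogeneity fields.  Passing the
benchmark therefore demonstrates that the pipeline machinery works and that
the hybrid design helps *under these conditions*; it is not evidence of
clinical-grade accuracy.

## 5. Benchmark design

The cohort design follows the study layout: 50 labelled volumes split
60:20:20 (floor, remainder to train) into 30 train / 10 validation / 10
test, plus 20 unlabelled volumes pseudo-labelled by the pipeline — a
50-volume training pool.  Phantom conditions were chosen so the variational
stage operates in its intended "good but not perfect" band (whole-lesion
Dice well below 1): noise σ 0.05, texture 0.03, boundary contrast jittered
in [0.10, 0.20], dropout in [0.2, 0.6], tube centre offset within ±3 mm,
radii, ellipse ratio/orientation and wobble frequency/phase all jittered so
30 labelled volumes undersample the shape family.  Problem sizes are
desk-scale by design: 24³ voxels at 1 mm, width-8 U-Net, 14 epochs — a full
benchmark (four method columns and all metrics) runs in minutes on one CPU
core.  The reported comparison columns are: variational-only
(estimate-seeded), propagated estimate, standard, hybrid; the reduced-data
experiment retrains the hybrid at decreasing labelled fractions against the
full-data standard.

A caveat this benchmark makes explicit: on a *parametric* phantom family,
every feature of the truth is either visible in the image (and then
learnable by the image-only standard network from 30 examples) or a random
latent no stage can recover, so the hybrid's margin over the standard
baseline is structurally much smaller here than on real anatomy — at these
conditions the two arms score within a few thousandths of each other, with
the hybrid clearly ahead of the variational-only and raw-estimate columns.
On real cohorts the estimate channel carries patient-specific context that
no population prior replaces; the phantoms cannot manufacture that without
smuggling it into the image.

## Numerical and degenerate-input conventions

* Metrics: both masks empty ⇒ DICE = JACCARD = VS = 1 (perfect-agreement
  convention); exactly one empty ⇒ DICE = JACCARD = 0 and HD undefined
  (NaN in reports; `hausdorff` raises on an empty set).
* Hausdorff distances are computed between boundary voxels (6-connectivity
  erosion difference) at voxel centres scaled by spacing; full-set and
  boundary HD coincide and the full-set all-pairs computation is the test
  oracle.
* Bland–Altman: bias = mean(measured − reference), limits ± 1.96 × sample sd
  (n − 1); at least two pairs required.
* Windowing clips to [low, high] then maps affinely to [0, 1]; slice crops
  are inclusive on both ends along z.  Windowing is idempotent.
* Volumes are reported both as voxel counts and mm³ (count × voxel volume).

## Known limitations

* The CNN is CPU-scale; training wall-clock grows linearly with voxels ×
  epochs, so realistic 512×512×N CT volumes require patch-wise training far
  beyond the bundled benchmark settings.
* The registration default is affine; strongly deformable inter-patient
  anatomy needs `affine+deformable`, and the demons stage carries no
  topology guarantees.
* The two-phase region model uses one scalar mean per side; regions whose
  complement mixes very different intensities (e.g. thrombus against
  background *and* bright lumen) rely on the distance prior and the edge
  term to stay local.
* The reduced-data comparison in the bundled tests uses the benchmark seed;
  averaging over several seeds (supported via the CLI) gives a more stable
  estimate at proportionally higher cost.
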