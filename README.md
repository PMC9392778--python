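# hybridseg

Hybrid variational + semi-supervised deep-learning segmentation of 3D
medical volumes, with synthetic CT-like phantoms and a complete
evaluation-metric suite.

## The problem

Serial follow-up of solid lesions — the motivating case is the stented
abdominal aortic aneurysm after endovascular repair (EVAR), imaged by
contrast CT — requires segmenting the same structures on scan after scan.
Manual segmentation is accurate but slow; purely variational methods need
per-scan seed points and minutes of compute; purely supervised CNNs need
large labelled training sets.  `hybridseg` implements a pipeline that
combines all three ingredients so that exactly **one** volume needs
interactive seeding:

1. **Variational initial segmentation** — a convex relaxed two-phase energy
   over u ∈ [0, 1],

       E(u) = ∫ g|∇u| + λ∫[u(I−c_in)² + (1−u)(I−c_out)²] + μ∫u·d(x),

   with an edge indicator g built from a local-contrast-normalized image
   (so weak boundaries still attract the contour), marker-seeded region
   means c_in/c_out, and a distance prior d from the seeds.  Solved by
   monotone projected gradient descent; thresholding at θ gives the mask.
2. **Registration propagation** — each further volume receives an *estimate*
   by classical multiresolution affine (optionally + demons) registration of
   the segmented reference onto it; no further user interaction.
3. **CNN refinement** — a small 3D U-Net receives the scan **and** the
   estimate as input channels (the `hybrid` configuration) and is trained
   semi-supervised: labelled volumes use their reference masks, unlabelled
   volumes use the variationally refined estimates as pseudo-labels.  The
   conventional `standard` baseline (scan-only input, labelled data only) is
   included for comparison.

Evaluation covers the standard quantities: confusion counts,
DICE = 2TP/(2TP+FP+FN), JACCARD = TP/(TP+FP+FN),
volumetric similarity VS = 1 − |FN−FP|/(2TP+FP+FN), directed and symmetric
Hausdorff distance in mm, sensitivity/specificity, Bland–Altman agreement,
and cohort summaries in both mean ± sd and median (range) conventions.

Everything is exercisable end-to-end on synthetic phantoms (bright
stent+lumen tube inside a low-contrast thrombus ring, tumour blobs, organ
superellipsoids) with exact ground truth, controllable contrast, noise and
simulated boundary-contrast dropouts.  See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import numpy as np
from hybridseg import (PhantomSpec, generate_phantom, MarkerSet,
                       solve_segmentation, binarize, evaluate_pair)

# a 32³ phantom: bright lumen tube in a low-contrast thrombus ring
spec = PhantomSpec(grid_shape=(32, 32, 32), lumen_radius_mm=3.0,
                   thrombus_outer_radius_mm=8.0, centerline_amplitude_mm=1.0,
                   noise_sigma=0.02, rng_seed=3)
ph = generate_phantom(spec)

# segment the thrombus from three seed points
markers = MarkerSet(inside=[(16, 16, 10), (8, 16, 9), (24, 17, 10)])
seg = solve_segmentation(ph.volume, markers)
mask = binarize(seg)

from hybridseg import LabelMask
report = evaluate_pair(mask, LabelMask((ph.truth.data == 1).astype(np.int16)))
print(f"dice={report.dice:.3f} jaccard={report.jaccard:.3f} "
      f"vs={report.vs:.3f} hd={report.hd_mm:.1f}mm")
```

prints

```
dice=1.000 jaccard=0.999 vs=1.000 hd=1.0mm
```

— at this mild noise level the thrombus ring is recovered essentially
exactly from three clicks; the volumetric similarity of 1 says the volumes
agree, and the largest boundary error is one voxel.  Lowering the contrast
and raising `noise_sigma`/`dropout_fraction` degrades this gracefully (the
benchmark below operates the solver around Dice 0.7–0.8, where the CNN
refinement earns its keep).

The full synthetic benchmark (50 labelled volumes split 30/10/10 plus 20
pseudo-labelled, comparing variational-only / estimate / standard / hybrid)
runs from the command line:

```bash
hybridseg benchmark --seed 7 --out report.json
hybridseg reduced-data --seed 7 --out reduced.csv
```

Other subcommands (`simulate`, `varseg`, `propagate`, `train`, `infer`,
`evaluate`) expose each stage separately on NIfTI volumes; see
`hybridseg --help`.

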