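# Methods

## The problem and the pipeline

Blunt hepatic trauma appears on portal-venous-phase contrast-enhanced CT as
hypodense regions (lacerations, intraparenchymal hematomas) inside an
otherwise enhancing liver.  The clinically useful quantity is the **liver
parenchymal disruption index**

    LPDI = 100% * V(trauma) / V(liver),

with both volumes obtained by voxel volumetry: true-voxel count of a binary
mask times the per-voxel physical volume taken from the scan's spacing
metadata.  `hepavol` implements the full cascaded workflow that produces
those masks automatically:

1. **Stage 1 — liver segmentation** of the whole scan;
2. **largest 3D connected component** of the initial liver prediction
   (26-connectivity by default; ties between equal-size components are
   broken toward the component encountered first in scan order, for
   determinism);
3. **dilation by a 5 mm physical margin**, computed as an exact Euclidean
   distance transform with the per-axis spacing — a structuring element of
   fixed voxel radius would be wrong on anisotropic grids (2 x 2 x 5 mm
   voxels are the default here);
4. **crop** to the tight bounding box of the dilated mask, with the voxel
   offset recorded so results re-embed exactly;
5. **histogram equalization** of the crop (256 bins).  The equalization map
   is fitted on the voxels inside the dilated liver mask and applied to the
   whole crop: fitting on the background would dilute the
   parenchyma/lesion contrast that the trauma stage depends on.  Fitting on
   the whole crop is available as an option;
6. **grayscale inversion** `v -> 1 - v` on the normalized range, so the
   hypodense lesions become the brightest structures;
7. **Stage 2 — trauma segmentation** in the cropped, preprocessed frame;
8. **re-embedding** through the recorded offset and **restriction to the
   predicted liver** (voxel-wise intersection) — blunt-trauma lesions are
   intraparenchymal by definition, so extrahepatic detections are discarded;
9. **volumetry and LPDI** from the final masks.

The geometry of steps 2–4 and 8 is exact: feeding ground-truth masks through
the chain reproduces them voxel for voxel (this is asserted in the tests).

## Segmentation backends

The two stages accept any callable from a volume to a mask.  Two families
are provided:

**Residual 3D U-Net.**  An encoder–decoder with residual blocks
(convolution -> instance normalization -> leaky ReLU, slope 0.01), two
blocks per resolution step, strided-convolution downsampling,
transposed-convolution upsampling (kernel = stride = 2), feature counts
doubling per downsampling from `initial_features`, concatenation skips, and
1x1-convolution output heads.  Auxiliary heads on the coarser decoder levels
give deep supervision; their losses are weighted by successive halving,
renormalized to sum to 1, against nearest-neighbour-downsampled targets.
Training minimizes `w_d * softDice + w_ce * BCE` (defaults 1 and 1) with
Adam.  The soft Dice uses an additive smoothing constant of 1e-5 in
numerator and denominator for stability on empty patches.  Patches are
sampled with a 50% foreground bias so small lesions stay represented.
Inference is sliding-window with half-patch stride and uniform overlap
averaging, binarized at probability 0.5.  Inputs are clipped to a
configurable intensity window and min–max scaled to [0, 1]; the default
window is (-50, 250) HU-like units for stage 1 and (0, 1) for stage 2, whose
input is already normalized by the equalization step.

The whole network — forward passes, backward passes, Adam — is implemented
in NumPy.  Convolutions are evaluated as a sum over kernel offsets of small
channel-mixing GEMMs on shifted views, and every layer's analytic gradient
is verified against finite differences in the test suite.  The default
configuration is deliberately desk-scale (3 levels, 8 initial features,
32^3 patches) so the full mechanism trains on a single CPU core in minutes;
the literature-scale setting (4+ levels, 32 features) is reachable through
the same configuration object but is not exercised by the tests.

**Intensity bands.**  A deterministic `[low, high]` threshold per stage.
These are reference backends that make the cascade, volumetry and cohort
statistics testable without any training.  Because histogram equalization
is a per-case monotone remap, a fixed band has no case-independent meaning
in equalized units; band backends therefore run with equalization and
inversion switched off (a pipeline flag) and are calibrated in raw units.
Model backends use the full preprocessing path.

## Synthetic phantoms

No patient data ships with the package; the phantom generator defines the
study conditions.  Each phantom is an ellipsoidal liver of bright
parenchyma (120 HU-like units) on a darker soft-tissue background (30),
containing hypodense lesions (parenchyma − 60) of two morphologies: rotated
ellipsoids (hematomas) and thin discs (lacerations), both clipped to the
liver.  Gaussian noise (SD 5) is added after an optional Gaussian
partial-volume blur.  The defaults:

| parameter | default | why |
|---|---|---|
| grid | 96 x 96 x 48 voxels | desk-scale stand-in for 512 x 512 acquisitions |
| spacing | (2, 2, 5) mm | preserves the 5 mm-slice through-plane anisotropy of abdominal CT |
| liver semi-axes | (60, 45, 55) mm | ~620 ml, a realistic pediatric liver volume |
| parenchyma / background / lesion offset | 120 / 30 / −60 | portal-venous enhancement regime; lesions hypodense |
| noise SD | 5 | visible noise without overwhelming a 30-unit class gap |
| blur sigma | 0 mm | see below |

Partial-volume blur is off by default and exercised explicitly where wanted:
a blurred liver boundary sweeps through the lesion intensity band, which
would contaminate any interior thresholding — the intensity-band reference
backends are only exactly calibratable on sharp phantoms.  The network
backends are trained and tested on the same conditions for comparability.

Lesion burden is specified as a target LPDI.  Exact analytic targeting is
impossible after clipping, so lesion sizes are scaled by bisection on a
global factor until the trauma/liver voxel ratio lands within ±1.5
percentage points of the target (typically much closer).  The truth masks
are the exact voxelizations used to paint the volume, so truth volumetry has
no estimation error by construction.

Graded cohorts draw a pseudo-grade I–V per case and a target LPDI uniformly
from non-overlapping, monotone bands — I [0.5, 2), II [2, 4), III [4, 12),
IV [12, 25), V [25, 40) percent — with liver size and lesion geometry
jittered per case.  The bands are a design choice that reproduces the
qualitative clinical picture (lesion burden rises with severity grade, the
low/high-severity boundary between grades II and III); they are not a claim
of clinical equivalence, and everything downstream that depends on them
(grade correlations, severity AUCs near 1, the location of the Youden
cutoff) should be read as a mechanism check, not a performance claim.

What the phantoms do **not** emulate: surrounding organs and vessels of
similar attenuation, contrast-phase variability, motion and beam-hardening
artifacts, irregular liver shapes, and lesions with ill-defined margins.
Passing tests therefore show that the pipeline's geometry, volumetry and
statistics are correct and that the learning mechanism works — not that the
desk-scale network would reach literature-level accuracy on real scans.

## Evaluation and statistics

Segmentation quality uses the four standard overlap metrics in percent:
Dice `2|S∩G|/(|S|+|G|)`, recall `|S∩G|/|G|`, precision `|S∩G|/|S|`, and the
signed relative volume difference `(|S|−|G|)/|G|`.  Two empty masks count as
Dice 100 (agreement on absence) with a warning; an empty prediction or
reference makes precision/recall undefined and raises.  Per-grade tables
report mean ± sample SD; single-case strata report SD 0 with a flag.

Cohort statistics: Spearman rank correlation (midrank ties; exact
permutation p-value for n ≤ 10, t-approximation above), Pearson r, ordinary
least squares with R², and ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed from the two-way ANOVA mean squares.
ICC(2,1) is the variant that penalizes systematic offset between manual and
automated measurement, which is the agreement question here.  Severity
discrimination (low = grades I–II, high = III–V) uses the Mann–Whitney AUC
(ties counted 1/2) with a DeLong 95% CI by default (deterministic) or a
seeded stratified bootstrap (2000 replicates).  Optimal cutoffs maximize
Youden's J over the observed score values with the `score >= cutoff`
positive rule; ties in J break toward the smaller (more sensitive) cutoff.
All p-values are two-sided.

## Cross-validation harness

`make_folds` produces a balanced, seed-deterministic, patient-wise k-fold
partition (fold sizes differ by at most one; duplicate ids are rejected).
The assignment is per patient, never per slice, so no case can leak across
folds.

## Numerical and degenerate-input conventions

* Volumes are float32; geometry (spacing, origins) float64.
* Voxel centers sit at `(i + 0.5) * spacing` from the grid origin; the same
  convention drives phantom voxelization and physical dilation, which is
  what makes the geometry chain exact.
* Constant crops equalize to a constant; inversion requires [0, 1] input.
* An empty stage-1 liver mask marks the case failed rather than raising;
  failed cases are listed in cohort reports, never dropped silently.
* All randomness (phantom painting, cohort jitter, weight init, patch
  sampling, bootstrap) flows from explicit integer seeds; identical seeds
  give bit-identical phantoms and reproducible training on one device.

## Problem sizes used by the test suite and acceptance script

Phantom cohorts of 50 cases at 96 x 96 x 48; training checks on one 64^3
phantom (75–200 Adam steps) and a 30-case cohort at 64 x 64 x 32 split
20 train / 10 test; oracle equivalence on 8^3–32^3 grids and samples of
n ≤ 30.  These sizes are the package's desk-scale study conditions.

## Known limitations

* The NumPy network trains at desk scale only; no GPU path, no mixed
  precision, no automatic architecture configuration.
* No hole filling or morphological smoothing beyond largest-component
  extraction; no isotropic resampling (the cascade operates on the native
  grid); no partial-volume-aware (fractional) volumetry.
* DICOM support is read-only and assumes one axial series per directory.
* The phantom realism limits listed above.
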