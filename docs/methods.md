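# Methods

## Problem and model

`boxsup3d` trains a voxel-wise tumor segmentation network when the only
annotation available per study is an axis-aligned 3D bounding box around the
tumor. The box splits each volume into two regions:

- **S0**, outside the box: every voxel is known background ("positive" class,
  label 0);
- **S1**, inside the box: a mixture of tumor and background voxels
  ("unlabeled", label 1).

Treating box labels as voxel ground truth (the *naive* objective, plain
sigmoid cross-entropy on the box labels) systematically teaches the network
to call near-boundary background "tumor", inflating predictions toward the
box. The package instead casts the problem as positive-unlabeled (PU)
classification. With class prior `pi_p` (the background fraction), per-voxel
losses `L(z, y)` (sigmoid cross-entropy on logit `z`), and empirical risk
terms formed from a mini-batch

    r_p_plus  = mean_{y=0} L(z, 0)     background voxels scored as background
    r_u_minus = mean_{y=1} L(z, 1)     unlabeled voxels scored as tumor
    r_p_minus = mean_{y=0} L(z, 1)     background voxels scored as tumor

the unbiased PU risk is

    R_pu  = pi_p * r_p_plus + (r_u_minus - pi_p * r_p_minus)

which estimates the fully supervised risk without any tumor labels. Flexible
networks drive the correction term `r_u_minus - pi_p*r_p_minus` negative by
memorizing the unlabeled region; the non-negative variant clamps it:

    R_nnpu = pi_p * r_p_plus + max(0, r_u_minus - pi_p * r_p_minus)

Optimization follows the gradient-switching rule: while the correction term
is at least `-beta`, ADAM steps on the gradient of the PU objective with
step scale `eta`; when it falls below `-beta`, the optimizer instead ascends
the correction term (gradient of `pi_p*r_p_minus - r_u_minus`) with the
discounted scale `gamma*eta`, backing the network away from the overfitted
regime. Defaults `pi_p = 0.75`, `beta = 0`, `gamma = 1`, `eta = 0.5` are the
method's standard operating point; `pi_p` can alternatively be recomputed
per cohort from box/volume voxel counts (`class_prior`), and a `shared_n`
switch divides all three risk terms by the full batch size instead of their
own label-group sizes for comparison.

### Averaging and sign conventions

The empirical risk terms average each loss over its own label group (the
convention of the non-negative PU estimator this objective follows); with
group averaging the prior `pi_p` enters exactly once per term. All losses
are standard non-negative cross-entropies computed in overflow-free
softplus form; the positive class is label 0 (background) throughout.

## Data pipeline

**Normalization.** Per channel, voxels with value exactly 0 are treated as
non-brain background and excluded; brain voxels are z-scored to zero mean
and unit *population* variance, background stays 0. Population rather than
sample variance is pinned so tests are deterministic; at volume scale the
difference is negligible.

**Boxes.** `box_from_mask` returns the tight axis-aligned box of a mask in
0-based half-open `[low, high)` convention (composes directly with array
slicing); a symmetric margin parameter (default 0) loosens it, since how
"rough" a clinical box is cannot be pinned down in general.

**Patch sampling.** Candidate centers are drawn uniformly over the volume;
exactly `round(n_selected * fraction_s1)` centers come from inside the box
and the rest from outside (stratified uniform subsampling — the simplest
rule consistent with the 0.8/0.2 proportions; the split is exact by count,
not in expectation). Patches use the floor-center convention for even
sides; out-of-volume voxels are zero-filled. Labels are 1 exactly on voxels
whose absolute coordinate lies in the box; a patch whose window exceeds the
box carries the analytic box-window intersection as its positives, and S0
patches carry all-zero labels. An optional minimum-nonzero-fraction filter
(off by default) can reject patches with little brain content.

**Multiscale input.** For each modality the network receives the native
`d`-patch plus a `2d`-patch at the same center resampled to side `d` with
trilinear interpolation — 8 channels for 4 modalities — adding coarse
context without enlarging the receptive field.

## Network

A compact 3D U-Net on NumPy arrays: per stage two 3x3x3 convolutions with
instance normalization (no affine parameters) and ReLU; 2x max pooling down,
nearest-neighbor upsampling and skip concatenation up; a 1x1x1 head emits
one logit per voxel. The deepest pooling stage of the reference 3D U-Net is
omitted (shallow depth default), preserving edge detail at patch scale. The
sigmoid lives inside the loss and the metrics, never in the network.

Convolutions and their backward passes are computed as one GEMM per kernel
tap on the flattened zero-padded volume with shift-and-add accumulation;
gradients were verified against central finite differences to 1e-9 relative
error (see `tests/test_unet3d.py`). The ADAM optimizer is the standard
formulation with bias correction; `eta` and `gamma*eta` act as per-step
multiplicative scales on its learning rate.

Desk-scale defaults: patch side 16, depth 2, 8 base filters (~90k
parameters); the full-scale preset (side 48, 40,000 candidate centers,
batch 64) is expressible through the same configs but is not exercised by
the test suite.

## Inference

Whole-volume prediction tiles the normalized volume with multiscale patches
at stride `d/2` (plus a final tile flush with each face), averages sigmoid
probabilities over overlapping tiles, and thresholds at 0.5. Voxels that
are exactly 0 in every channel — outside the brain by construction — are
assigned probability 0: on all-zero input the network output degenerates
to its bias and is not a prediction. Mean blending
at half-patch stride is the least-surprising default; both are exposed in
config. Predicted masks are post-processed by filling interior cavities
(6-connectivity) before scoring.

## Metrics

- **Dice**: `2|A∩B| / (|A|+|B|)`; two empty masks score 1.0, an empty
  prediction against a nonempty truth scores 0.
- **Hausdorff**: the symmetric max-min form — the largest distance from a
  point of one set to its nearest point in the other, maximized over both
  directions. (A printed max-max variant of this definition circulates; it
  equals the set diameter and contradicts the "nearest point in the other
  set" prose, so the max-min form is implemented.)
- **Hausdorff95**: each directed distance's 95th percentile (linear
  interpolation between order statistics) replaces the max, then the two
  directions are combined by max; by construction Hausdorff95 <= Hausdorff.

Distances are between foreground voxel centers scaled by voxel spacing
(mm); surface-only point sets are available as a speed option and give
identical values for the directed max. Undefined distances (either mask
empty) are recorded as missing and excluded from means with a count, never
as 0 or infinity.

**Cohort aggregation** draws `n_folds` (default 5) independent seeded 80/20
splits and reports each metric's mean across the evaluation subset of every
fold, then mean +/- std across folds. Folds whose evaluation subset has no
tumor-bearing volume are skipped with a warning.

**Region-grow baseline**: a learning-free reference that floods 6-connected
neighbors from the box center on the normalized FLAIR channel while the
absolute difference to the running region mean stays below 0.5 (gray-level
discontinuity threshold). Seeding at the box center keeps the baseline as
weakly supervised as the main method.

## Synthetic phantoms

Each phantom emulates a preprocessed 4-modality study: a spherical "brain"
(radius 0.8 of the half-side) of mean intensity 1.0 over an exactly-zero
background, one tumor per study built as a union of 1-3 overlapping
axis-aligned ellipsoids (semi-axes 6-12 voxels; satellites centered inside
the primary ellipsoid so the mask is 6-connected), per-channel additive
tumor contrast (+1.0, +0.8, -0.3, +0.5 — FLAIR/T2 hyperintense, T1 mildly
hypointense, T1ce enhancing) and i.i.d. Gaussian noise of SD 0.2. Cohorts
jitter tumor size, position and contrast per patient from a single seed;
regeneration is bit-identical.

What the phantoms deliberately do **not** model: MRI bias fields, partial
volume effects, multi-site intensity variation, non-ellipsoidal infiltrative
margins, or tumor sub-regions. Passing the end-to-end test therefore shows
that the PU objective recovers sub-box structure the naive objective
cannot, under the method's own assumptions — not that any particular Dice
level transfers to clinical data.

## Desk-scale study in the tests and acceptance script

The end-to-end comparison trains PU and naive objectives under one shared
configuration — 12 phantoms of 64^3 (9 train / 3 held out), 100 patches per
patient at side 16, batch 8, 3 epochs, ADAM 1e-3 with `eta = 0.5`, averaged
over 2 training seeds — and evaluates held-out whole-tumor Dice and the
predicted/true volume ratio. These sizes are the package's desk scale,
chosen so the whole suite runs on a single CPU core.

Two empirical regularities of this desk scale are worth knowing. First,
the schedule matters: the PU objective needs enough steps to prune the
in-box background (early on it over-segments like the naive objective),
but with the fixed prior `pi_p = 0.75` overstating the background fraction
inside these tight ellipsoid boxes (truth ~0.5), prolonged optimization
(roughly 2-3x the default step count) over-suppresses the unlabeled region
and can collapse predictions entirely; the 3-epoch schedule sits in the
regime where the method behaves as intended. Second, the two objectives
separate more reliably in volume calibration than in Dice: naive training
consistently predicts a larger multiple of the true tumor volume than PU
training does, while the held-out Dice difference fluctuates in sign with
cohort and training seed at this cohort size. Ellipsoidal tumors flatter
the naive baseline — a box-shaped prediction around a tumor filling half
its box already achieves Dice ~0.68 — so a Dice advantage for PU of the
size reported on clinical data should not be expected from these phantoms;
the volume-ratio ordering is the phantom study's robust readout.

## Numerical choices and edge cases

- Losses and risk components are computed in float64 regardless of network
  dtype; training tensors are float32.
- Single-class batches cannot yield PU risk components; the trainer skips
  such batches (rare under stratified sampling) and `risk_components`
  raises with a pointer at sampler-level mixing.
- A NaN objective aborts training with the offending step's record.
- Max-pool gradient splits equally among tied maxima; upsampling is
  nearest-neighbor with block-sum backward.
- `pi_p` validation is strict (`0 < pi_p < 1`); a box covering the whole
  volume is rejected rather than yielding a prior of 0.

## Known limitations

- The NumPy network is CPU-bound and desk-scale; clinical-scale training
  (48^3 patches, depth-3+ networks, hundreds of patients) is out of reach
  of this implementation and of the phantom generator's realism.
- `pi_p` is global and constant during training; per-patch priors are not
  estimated (the `class_prior` helper supports per-cohort recomputation).
- The region-grow baseline is a flood fill with a fixed threshold, not a
  full watershed transform.
- Data augmentation, early stopping and learning-rate schedules are
  intentionally absent.
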