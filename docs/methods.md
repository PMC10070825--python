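# Methods

## Problem and scope

`cardioseg` segments 2D short-axis cardiac MRI slices into four classes —
background, right ventricular blood pool (RV), myocardium (myo), and left
ventricular blood pool (LV) — with an encoder–decoder convolutional
network, and scores segmentations with the three accuracy measures standard
in cardiac segmentation work: the Dice overlap coefficient, the Hausdorff
distance (HD), and the average symmetric surface distance (ASSD).  Because
clinical short-axis data with expert contours is rarely redistributable,
the package ships a synthetic phantom generator that produces images with
exact gold-standard masks, so the entire pipeline — generation, training,
prediction, evaluation — runs and is tested end-to-end without any external
data.

## Network

The network is a U-Net: an encoder of `depth` stages, each applying two
same-padded 3×3 convolutions — every convolution followed by batch
normalization and ReLU — then 2×2 max pooling with stride 2, doubling the
feature channels per stage from `base_channels`.  The decoder mirrors the
encoder: a learned 2×2 stride-2 transposed convolution doubles the grid and
halves the channels, the result is concatenated with the matching encoder
output, and two more conv–BN–ReLU pairs follow.  A 1×1 convolution maps to
four logits and a per-pixel softmax yields class probabilities; the
predicted mask is the per-pixel argmax, with ties broken toward the lowest
class index.

Same-padding keeps output size equal to input size, so no cropping of skip
connections is needed and masks align pixel-for-pixel with the input.  The
reference configuration uses `base_channels=64`; `depth` defaults to 4 (the
classic choice) and is configurable since there is no single canonical
value.  A fixed-bilinear-interpolation + 1×1-projection upsampler is
available as `up_mode="bilinear"` for comparison with the learned
transposed convolution.

All layers are implemented directly in NumPy with hand-derived backward
passes: convolutions as im2col + one BLAS matrix product (the input
gradient is itself a same-padded correlation with the spatially flipped,
channel-transposed kernel — the exact adjoint under zero padding), max
pooling with first-element tie-breaking, and the transposed convolution as
a single matmul because kernel and stride coincide.  The test suite pins
each backward pass to its forward map through exact adjoint identities
⟨Jd, u⟩ = ⟨d, Jᵀu⟩, which are sharper than finite differences (the loss
surface is piecewise smooth, so finite differences across ReLU/pool kinks
are unreliable for deep layers).

Weights are He-uniform initialized (fan-in of the receptive field), BN
scale/shift start at γ=1, β=0; all randomness flows from a single integer
seed through `numpy.random.SeedSequence`.

## Batch normalization

Training mode standardizes each channel by the batch mean μ_B and the
*biased* batch variance σ²_B (divisor m, the number of activations pooled
per channel over batch and spatial axes):

    x̂ = (x − μ_B) / √(σ²_B + ε),   y = γ x̂ + β.

ε (default 1e-5) is added under the root — its purpose is to keep the
denominator positive when a channel's batch variance vanishes, which only
addition achieves.  Exponential running averages of (μ_B, σ²_B) with
momentum 0.1 replace the batch statistics at inference.  Train-mode calls
require at least two elements per channel; this is why the training batch
size must be ≥ 2.

## Losses

Training minimizes the compound loss

    L = α · L_CE + β · L_Dice,   α = 1, β = 0.2.

L_CE is per-pixel 4-way cross-entropy against a one-hot target, averaged
over pixels (mean, not sum, so the α:β balance is independent of image
resolution — the reduction had to be fixed as a design choice).
Probabilities are clamped at 1e-12 inside the logarithm.

L_Dice = 1 − 2|A·B| / (|A| + |B| + ε_d) is a soft Dice loss computed over
the three foreground classes jointly by default: its role is to protect the
small foreground structures that pixel-frequency-weighted cross-entropy
underserves, and the joint form does that with a single stable ratio.  A
per-class-averaged variant (`dice_mode="per_class"`) is provided; on
non-degenerate masks the two differ little, and the choice is exposed
rather than hidden.  ε_d defaults to 1e-10.  Both losses and their
analytic gradients with respect to the predicted probabilities are
accumulated in float64 so closed-form values (e.g. log 4 for a uniform
prediction) hold to ~1e-9; the gradient is chained through the softmax
explicitly.

## Optimization and augmentation

ADAM with learning rate 0.001, β₁=0.9, β₂=0.999, eps=1e-8; batch size 4;
18 epochs; no schedule, weight decay or early stopping.  The only model
selection is the checkpoint with the best validation Dice (mean over the
three foreground classes); validation uses the held-out test subjects,
logged as such — there is no third split.

Augmentation is applied on the fly per batch element and never written to
disk: independent horizontal/vertical flips, rotation uniform in ±15°, and
a random crop retaining 80–100% of the field of view, resized back to the
network input size.  Image and mask receive the identical geometric
transform; the image interpolates linearly while labels are always resampled
nearest-neighbor so classes never blend.  A draw that would erase all
foreground pixels is redrawn (at most 5 times, then identity).  The ±15°
and 0.8–1.0 ranges are modest defaults chosen to keep the anatomy in frame;
both are configurable.

Inputs are min–max scaled to [0, 1] per slice before the network.  This
normalization is a package choice (it makes phantom and real intensity
scales commensurate), documented rather than claimed universal.

## Evaluation metrics

For a gold-standard region A and prediction B on the same grid:

* **Dice** = 2|A∩B| / (|A|+|B|), with Dice = 1 when both regions are empty
  (nothing to find, nothing found).
* **HD** = max( max_{a∈S(A)} d(a, S(B)), max_{b∈S(B)} d(b, S(A)) ): the
  exact maximum, not a 95th percentile.
* **ASSD** = [ Σ_{a∈S(A)} d(a,S(B)) + Σ_{b∈S(B)} d(b,S(A)) ] / (|S(A)|+|S(B)|).

S(·) is the surface: region pixels with at least one 4-connected neighbor
outside the region, the image border counting as outside (`surface_pixels`
also accepts `connectivity=8`).  Both HD and
ASSD are computed between surface sets — ASSD is surface-based by
definition, and using the same point sets for HD keeps the two distances
comparable, matching common practice in cardiac segmentation challenges.
Nearest distances come from an exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`), with per-axis `sampling` applying
anisotropic pixel spacing before the Euclidean metric; the tests verify
exact agreement with brute-force all-pairs search.  Distances are reported
in mm when a spacing is supplied and in pixels otherwise, and the report
labels its units explicitly.

Degenerate cases: an empty predicted region scores Dice 0 against a
nonempty gold standard (a miss is penalized), but HD/ASSD are undefined
without two surfaces and are reported as NaN sentinels that the report
excludes from averages, with an exclusion count — fabricating a distance for
a missing structure would corrupt the averages in either direction.

The report table has one row per (structure ∈ {LV, RV, myo}, phase ∈ {ED,
ES, mean}); per-phase values average over that phase's slices and the mean
row is the arithmetic mean of the ED and ES rows.

## Synthetic phantom

The phantom is a stylized mid-ventricular short-axis slice built from
analytic geometry at pixel-center coordinates: the LV blood pool is a disc,
the myocardium a closed annulus of constant thickness around it, and the RV
a crescent — an annular sector of limited arc hugging the epicardial border
on the anatomical right (leftward in the image).  Precedence LV > myo > RV >
background is structural: the three regions occupy disjoint radial shells.

Cardiac motion is modeled by shrinking the LV radius linearly from its
end-diastolic value at phase 0 to (1 − contraction_fraction)× that at the
last phase (default 5 phases, contraction 0.25–0.45 across subjects); the
annulus and crescent ride on the shrinking radius.  The image assigns each
class its mean gray level plus i.i.d. Gaussian noise.  Defaults (background
30, myocardium 90, RV 180, LV 200, σ = 15) follow the appearance of
balanced-SSFP cine, where blood is bright and muscle mid-gray; the RV pool
is set slightly darker than the LV, as flow and partial-volume effects
commonly render it, which also prevents the two blood pools from being
trivially separable by intensity alone — the network has to use geometry.
Per-subject variation samples radii, wall thickness, crescent arc,
contraction, center jitter and anisotropic pixel spacing (0.70–1.92 mm,
the printed in-plane resolution range of the kind of hospital short-axis
data this emulates) from uniform intervals.  An optional
`small_structure_scale` shrinks all radii to emulate near-apical slices
with very few ventricular pixels.

What the phantom does *not* emulate: Rician noise statistics, intensity
bias fields, k-space/motion artifacts, trabeculation, papillary muscles,
through-plane anatomy, or inter-observer contour ambiguity.  Noise is
Gaussian rather than Rician deliberately — it is adequate for exercising
the optimization and keeps the zero-noise case an exact identity
(image = intensity_mean[mask]), which the tests rely on.  Consequently,
passing phantom experiments demonstrates that the implementation trains,
generalizes across subject-level splits and is scored correctly; it does
not certify clinical-grade accuracy on hospital data.

## Reference experiment

The packaged end-to-end experiment (`run_experiment`, also what
`scripts/acceptance.py` runs) uses 40 subjects × 5 phases at 64×64, split
8:2 by subject, and a reduced network (depth 3, base 16, ~0.48M parameters)
under the reference schedule (ADAM lr 0.001, batch 4, 18 epochs, compound
loss, augmentation on).  These sizes keep a single run around a few minutes
on one CPU while leaving a wide margin above the acceptance thresholds
(held-out mean Dice ≥ 0.90 LV, ≥ 0.80 RV/myo averaged over 3 seeds);
typical results are ≈ 0.99 (LV), 0.99 (RV), 0.98 (myo).

## Numerical and design notes

* Argmax ties (exactly equal probabilities) go to the lowest class index —
  deterministic and biased toward background, the conservative choice.
* `train` refuses a configuration whose last batch would contain a single
  element (train-mode BN cannot standardize it); sizes divisible by the
  batch size, or remainders ≥ 2, are unaffected.
* Training is bit-reproducible for a fixed seed on a fixed platform: data
  generation, splitting, initialization, shuffling and augmentation each
  draw from seeded generators, and the train log records the seed and a
  hash of the resolved configuration.
* Dataset splits are by subject, and the train log stores both subject
  lists so leakage is auditable after the fact.
* Checkpoints are single-file NPZ archives with an embedded versioned
  config, including all BN running statistics.
* Mask files store class indices, never colors; the fixed RGB palette used
  by the optional overlay writer is presentation only.

## Known limitations

* 2D only: no volumetric context, no 3D metrics, no clinical indices
  (ejection fraction, mass).
* The NumPy implementation is single-node, CPU-bound and intended for
  method study and small experiments, not large-scale training.
* The per-class Dice-loss variant and 8-connected surfaces exist but are
  not exercised by the reference experiment.
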