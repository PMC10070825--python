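# cardioseg

Segmentation of short-axis cardiac MRI slices into left ventricle (LV),
right ventricle (RV), myocardium and background with a batch-normalized
U-Net, plus the standard accuracy metrics of the field and a synthetic
phantom generator with exact gold-standard masks.

**Who it is for.** Researchers studying cardiac segmentation methodology —
the interplay of network topology, batch normalization, and compound loss
functions — who need a fully inspectable, reproducible pipeline that runs
end-to-end on a single CPU without access to clinical data.

## Method

The segmenter is an encoder–decoder network: each encoder stage applies two
3×3 convolutions, every convolution followed by batch normalization

x̂ = (x − μ_B)/√(σ²_B + ε),  y = γx̂ + β

and ReLU, then 2×2 max pooling while doubling the feature channels; the
decoder mirrors it with learned 2× upsampling, skip concatenation, and a
final 1×1 convolution to four softmax classes.  Training minimizes the
compound loss

L = α·L_CE + β·L_Dice,  α = 1, β = 0.2,

where L_CE is pixel-wise cross-entropy and L_Dice = 1 − 2|A·B|/(|A|+|B|+ε_d)
is a soft Dice loss over the foreground classes, optimized with ADAM
(lr 0.001, batch 4, 18 epochs) under on-the-fly crop/rotate/flip
augmentation.  Evaluation reports, per structure and cardiac phase
(end-diastole ED, end-systole ES):

* Dice overlap 2|A∩B|/(|A|+|B|),
* Hausdorff distance max(max_a min_b d(a,b), max_b min_a d(b,a)) between
  boundary pixel sets,
* average symmetric surface distance (ASSD), the mean nearest-boundary
  distance over both contours,

with anisotropic pixel spacing applied before the Euclidean metric.  The
network, batch normalization, losses and their gradients are implemented
directly in NumPy (im2col convolutions, hand-derived adjoints), so every
computational step is inspectable and unit-tested; see `docs/methods.md`.

Because clinical short-axis datasets are generally private, the package
generates stylized mid-ventricular phantoms — LV disc, myocardial annulus,
RV crescent, with the LV radius contracting linearly from ED to ES over
five phases, per-class intensities plus Gaussian noise, and in-plane
spacing sampled from 0.70–1.92 mm — so the whole pipeline is trainable and
verifiable against exact ground truth.

## Worked example

```python
from cardioseg.training import run_experiment

# 40 synthetic subjects x 5 phases at 64x64, split 8:2 by subject,
# depth-3/base-16 network, ADAM lr 0.001, batch 4, 18 epochs
report, log, network = run_experiment(phantom_seed=1, n_subjects=40)
print(report.table.round(3))
```

prints (about 3–4 minutes on one CPU):

```
                  dice     hd   assd  n_slices  n_excluded
structure phase
LV        ED     0.997  1.159  0.051         8           0
          ES     0.998  0.730  0.018         8           0
          mean   0.997  0.945  0.034        16           0
RV        ED     0.992  1.228  0.049         8           0
          ES     0.988  1.219  0.052         8           0
          mean   0.990  1.224  0.050        16           0
myo       ED     0.978  1.339  0.119         8           0
          ES     0.979  1.228  0.108         8           0
          mean   0.978  1.284  0.113        16           0
```

Each row scores the 8 held-out test slices of one phase: `dice` is overlap
with the gold standard (1 = perfect), `hd` the worst-case and `assd` the
average boundary disagreement in mm, and the `mean` row averages ED and ES.
`n_excluded` counts slices where a surface distance was undefined (empty
predicted structure).  The same estimator is available with a
scikit-learn surface:

```python
from cardioseg import UNetSegmenter
est = UNetSegmenter(depth=3, base_channels=16, input_size=64).fit(X, y)
masks = est.predict(X_new)          # (n, H, W) labels in {0, 1, 2, 3}
```

## Command line

```sh
cardioseg generate --subjects 10 --seed 1 --out data/
cardioseg train    --manifest data/manifest.csv --out run/ --seed 1
cardioseg predict  --manifest data/manifest.csv --checkpoint run/checkpoint.npz --out pred/
cardioseg evaluate --pred-manifest pred/predictions.csv --gt-manifest data/manifest.csv --out eval/
```

Images and masks travel as NIfTI (spacing in the header) or PNG; every run
directory contains the resolved config, seed, library versions and input
manifest hash.

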