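# Methods

## Problem and model

The task is four-way classification of shoulder-implant radiographs by
manufacturer (Cofield, Depuy, Tornier, Zimmer).  The clinical collection
this protocol was designed around holds 597 de-identified scans (83, 294,
71, 149 per class) — one scan per patient, so image-level and patient-level
splits coincide.  The package implements the full method; the clinical data
themselves are an optional input.

**Subnets.**  IFC-Net is Inception-V3 truncated before global average
pooling (terminal map 8×8×2048, 299×299×3 input); MFC-Net is MobileNet-V2
truncated the same way (7×7×1280, 224×224×3).  Grayscale radiographs are
replicated to three channels, resized bilinearly per branch, and
standardized with mean 0.5 and scale 0.25 on the [0, 1] intensity range.

**CP block.**  Each subnet replaces global average pooling with a
convolution-pooling head: `conv(n_filters=50, kernel = full spatial extent)
→ BN → ReLU → FC(64) → ReLU`.  With the default `valid` padding the
convolution collapses the terminal map to 1×1×50, so the FC consumes 50
inputs; a `same` mode (conv output keeps the spatial size, FC consumes
spatial²·50) is available.  `valid` is the default because it is the only
reading consistent with the architecture's printed parameter totals
(28.4 M / 34 M, below); the narrative description of an 8×8×50 activation
map is treated as describing the filter bank.

**JMLP.**  Fusion concatenates the two 64-dim features (f_I first) into
f_IM ∈ R¹²⁸ and applies FC-64 → FC-64 → FC-4 → softmax.  ReLU follows FC-1
and FC-2 by default (`activation=False` gives the plain linear stack, which
would collapse to a single linear map; whether the original design used
inter-layer activations is not documented, so both are supported).  Argmax
ties resolve to the lowest class index; classes are ordered
lexicographically by directory name (Cofield = C1 … Zimmer = C4).

## Parameter accounting

`count_parameters` counts trainable scalars: convolution and FC weights and
biases plus batch-norm scale/shift; batch-norm running statistics are
buffers and excluded.  Convolution layers carry biases even when followed
by batch normalization — the convention of the MATLAB deep-learning stack,
and the one under which the default builds reproduce the printed totals:

| network | exact count | rendered |
|---|---|---|
| IFC-Net (with 4-class head) | 28,360,058 | 28.4 M |
| MFC-Net (with 4-class head) | 5,380,602 | 5.4 M |
| IMFC-Net (feature paths + JMLP) | 33,752,816 | 34 M |
| JMLP alone | 12,676 | — |

With the torch-style bias-free convention (`conv_bias=False`) the feature
extractors instead reproduce the published base-architecture totals
(Inception-V3 23,834,568 with its 1000-class FC and no auxiliary head;
MobileNet-V2 3,504,872 with its classifier), which the test suite uses as an
independent cross-check of the layer definitions.  The two conventions
differ by exactly one scalar per convolution output channel (17,216 /
17,056).  Note the MFC-Net count is sometimes quoted as 5.5 M; neither
padding mode reproduces that rounding exactly, so no check is pinned to it.

## Training

Cross-entropy loss, mini-batch SGD with learning rate 0.001 (constant),
momentum 0.9, L2 regularization 1e-4 applied to all weights except
batch-norm scale/shift, batch size 10.  L2 decay is added to the gradient
before the momentum buffer.  A step learning-rate schedule is available
behind `lr_drop_factor`/`lr_drop_period` but off by default: a drop factor
without a stated drop period is not actionable, and the constant rate is the
minimal faithful reading.  Default epochs: 13 for each subnet, 4 for the
JMLP stage, 13 end-to-end.  Final-epoch weights are kept (no early model
selection); per-epoch train/val accuracy and loss histories are recorded.
Data order is reshuffled each epoch with a seed derived from
(run seed, epoch), so runs are bit-reproducible.

Sequential training freezes the trained subnets (gradients never reach
them; their batch-norm layers run on inference statistics) and trains the
JMLP from scratch on the concatenated features.  The freezing contract is
enforced by SHA-256 checksums of the parameter state before and after the
fusion stage.  Because frozen subnets with fixed inputs produce constant
features, those features are computed once and cached, which makes the
fusion stage nearly free.  End-to-end training updates every parameter
jointly and exists for the sequential-vs-joint comparison.

Pretrained backbone weights are an optional input (an npz state dict);
requesting `pretrained=True` without a weight source is an explicit error —
random initialization must be opted into, never silently substituted.
Initialization is Glorot-uniform with zero biases, deterministic per seed.

## Evaluation protocol

Splits are k = 10 independent stratified draws at fractions 0.90/0.02/0.08:
test and validation sizes are `round(0.08·n)` and `round(0.02·n)`
(half-up), apportioned across classes by largest remainder (stratification
within one record per split), training absorbs the rest; 597 records give
537/12/48 per fold.  Ten disjoint 8% test blocks cannot tile a dataset, so
independent draws — not a partition — are the only consistent reading of
the protocol.  All compared models reuse the same folds, which is what
makes the per-fold metric lists pairable.

Metrics per fold: ACC = trace/total of the 4×4 confusion matrix; AP and AR
= unweighted macro means of per-class one-vs-rest precision and recall (a
never-predicted class contributes precision 0, with a warning); F1 = the
harmonic mean of AP and AR computed per fold and then averaged over folds.
The alternative (harmonic mean of the averaged AP/AR) is exposed as
`f1_of_means` because the two differ in general.  Aggregation is mean ±
sample standard deviation (n−1).  Model pairs are compared with two-sided
paired t-tests per metric (scipy `ttest_rel`; a two-sample option exists);
the four p-values are additionally averaged, with confidence verdicts at
0.05 and 0.01.  Rounding in reports is half-up, 2 decimals for metrics and
4 for p-values; raw values are kept in the CSVs.

## Augmentation

* **RIA** (rotational-invariant augmentation): offline rotated copies of
  each *training* image at fixed angles, default {45, 90, …, 315}°, i.e.
  eight orientations including the original.  The exact angle set of the
  original technique is not restated in the sources available here; uniform
  coverage of the circle is the package's default and the set is fully
  configurable.  Rotation is about the image center, exposed corners filled
  with 0 (radiograph backgrounds are dark).  Validation and test images are
  never augmented.
* **online**: per-iteration random rotation (±15°) and translation (±10% of
  the image size), both ranges conventional mild defaults and configurable.
* **none**: identity.

## Synthetic radiographs

The generator emulates the features the classifier relies on: a dark noisy
background (Gaussian noise σ = 6/255), a bright elongated stem, and a
humeral-head disc whose fixation-hole count (1–4) and fin count (0–3) are
class-specific, plus per-image rotation (±15°), translation, scale and
intensity jitter.  Rendering is analytic on a rotated coordinate grid, so a
seed reproduces images bit-identically.  Default per-class counts mirror the
clinical collection (83/294/71/149).

What it does *not* emulate: real intra-class variation in implant design
generations, projection/pose variation beyond in-plane rotation, anatomy and
soft-tissue context, detector artifacts, and the low inter-class visual
similarity that makes the clinical task hard.  Passing tests on synthetic
data therefore demonstrate that the pipeline's machinery (shapes, training
dynamics, protocol plumbing, interpretability taps) is correct — not that
clinical-level accuracy is attainable; the headline clinical metrics require
the real dataset and pretrained backbones and are out of desk-scale reach.

## Grad-CAM

Channel weights are the spatial mean of the class-logit gradient at a tap
layer; the map is the ReLU of the weighted channel sum, upsampled bilinearly
to the input and max-normalized per image (all-zero maps stay zero).  Tap
registries name five blocks per subnet: for the Inception branch the stem
and the four inception stages (A–E); for the MobileNet branch five
inverted-residual stage boundaries plus the final 1×1 expansion.  The
original MobileNet tap labels reference an appendix layer table that is not
available here, so the registry maps them to the corresponding stage outputs
of the published base architecture.

## Numerical and scale choices

The layer kit is float32 throughout; convolutions use kernel-offset
accumulation over BLAS matmuls (a 1×1 fast path covers most of
MobileNet-V2), batch-norm statistics are single-pass, and 'same' padding for
even kernels is asymmetric (k−1 total, extra row/column trailing).
Gradients of every op are validated against central differences.

Default problem sizes in the test suite are chosen so the whole suite runs
in a few minutes on one CPU: training-path tests use width-reduced backbones
(`width_mult` 0.25–0.5) at 64–96 px inputs, the convergence check trains a
full-width MFC-Net at 96 px on 40 images, and the scaled-down
cross-validated pipeline runs k = 2 folds on 160 synthetic images (subnet
epochs 10; the JMLP stage gets 40 epochs at this scale since 4 epochs of
~14 batches leaves the fusion undertrained, and cached frozen features make
the extra epochs free).  The acceptance script trains the full default
MFC-Net (224 px) on 40 synthetic images for up to 30 epochs, stopping once
an inference-mode pass over the training set reaches 100%.

## Known limitations

* No pretrained ImageNet weights ship with the package; clinical-level
  accuracy additionally needs the real dataset.
* Class imbalance is left unaddressed (no resampling or reweighting), as in
  the protocol this package implements; the largest class has 71.77% more
  samples than the smallest, the second largest 44.3% more.
* The CP head requires square terminal maps; backbones beyond the two
  families are extension hooks, not presets.
* Training is single-threaded CPU numpy: adequate for the desk-scale runs
  here, not for full 597-image, ten-fold, RIA-augmented training.
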