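# Methods

`fusionacl` implements a multimodal feature-fusion classifier for binary
tear prediction (ACL tear, meniscus tear) on 2-D knee-MRI-like slices, a
synthetic phantom generator to exercise it, and the concordance statistics
used to compare an imaging modality against an arthroscopic gold standard.
This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where the design was genuinely open.

## Phantom model

Each slice is a 64×64 (configurable, ≥ 32) image on a [0, 1] intensity
scale emulating a fluid-sensitive (T2-weighted) appearance: moderately
bright soft tissue (0.55), a dark ligament band (0.25) — diagonal in the
sagittal plane, vertical in the coronal plane, a small dark cross-section
disc in the transverse plane — and a dark meniscus wedge (0.30) near the
tibial side. A positive ACL label adds `lesion_contrast` (default 0.4) to
a gap across the band; a positive meniscus label brightens a thin line
crossing the wedge. Tears thus present as focal high signal interrupting a
low-signal structure, the qualitative radiological sign of an acute tear.
Geometry (band angle/offset/width, tear position/length, wedge pose) is
jittered per image; additive Gaussian noise (default sd 0.1; a Rician
magnitude mode is available) is applied last and the result clipped to
[0, 1]. Base intensities sit well inside (0, 1) so clipping is rare and
region means stay calibrated.

Every image records its sampled geometry and both lesion masks, including
for negatives, so tests can measure the realized contrast exactly: the
mean inside the lesion mask differs between positive and negative images
by `lesion_contrast` up to noise.

What the phantom does *not* emulate: partial-volume effects, coil
inhomogeneity, anatomy other than the two target structures, partial-tear
grades, 3-D continuity across slices. Passing tests therefore demonstrate
that the pipeline recovers a controlled, well-specified signal — not
clinical performance on patient data.

The defaults (n = 200 images, tear prevalence 0.5 per task, contrast 0.4,
noise 0.1) are the study conditions used by the acceptance checks and were
fixed before calibration of the classifier.

## Deep feature branch

A five-block VGG-style convolutional backbone (3×3 conv + ReLU stacks,
2×2 max pool between blocks) yields one feature map per block; the map of
block *g* is the output of its last convolution, with spatial side
`input_size / 2^(g-1)`. Blocks 2–5 are used by default, mirroring
transfer-learning practice of discarding the first block's near-raw
features. The backbone is frozen: weights come from a seeded He-scaled
initialization (zero biases) or from a user-supplied `.npz` checkpoint;
nothing downstream updates them. Random frozen convolutional features are
a standard, honestly-declared stand-in when no pretraining data is
available; at the phantom's signal strength they carry useful texture
information.

The maps are merged top-down as a feature pyramid: the coarser fused map
is upsampled 2× (nearest neighbour, exactly invertible for the 2× case), a
2×2 lateral convolution projects the finer raw map to a common channel
width (default 32), the two are summed pixelwise, and a 5×5 convolution
smooths the sum to suppress upsampling aliasing. The even 2×2 kernel uses
asymmetric zero padding (0 top/left, 1 bottom/right) so the pixelwise sum
is well defined; the 5×5 kernel uses symmetric padding 2. If an odd map
size makes the upsampled map one pixel too large/small it is cropped or
edge-padded by that one pixel (logged).

The finest fused map then passes through batch normalization (per-channel,
biased batch variance, ε = 1e-5; the pipeline uses a single full-batch
pass and adopts the training-set moments as the running statistics so
evaluation normalizes identically), ReLU, adaptive max pooling with
`stride = floor(In/Out)`, `kernel = In − (Out−1)·stride`, and a seeded
affine projection + ReLU to the deep vector *o*. The library default deep
dimension is 1026; the pipeline's desk-scale profile uses 64 (below).

## Traditional feature branch

The handcrafted vector *c* has 32 named features in a fixed, documented
order (`fusionacl.head.TRADITIONAL_FEATURE_NAMES`):

* 12 intensity histogram statistics (mean, sd, skewness, kurtosis, min,
  max, median, p10, p90, IQR, 64-bin Shannon entropy, uniformity);
* 6 gradient statistics (central differences: magnitude mean/sd/max/p90,
  mean absolute row/column derivative);
* 6 grey-level co-occurrence summaries (32 levels, distances 1 and 3,
  averaged over 0° and 90°: contrast, dissimilarity, homogeneity, energy,
  correlation at d=1; contrast at d=3);
* 8 dark-structure shape features computed on a Gaussian-denoised copy
  (σ = 1.5): dark-area fraction, component count, largest and
  second-largest component area fractions, largest-component
  eccentricity, minimum smoothed intensity, smoothed p95 and p99. The
  dark mask thresholds at the midpoint of the smoothed 5th and 60th
  percentiles, so the mask — and every shape feature derived from it — is
  invariant to a constant intensity offset.

The dark-structure subset is the deliberately clinical part: ligament
discontinuity (the largest dark component splitting) is the defining sign
of a complete tear, and component count/area react to it directly.
Degenerate (constant) images report undefined statistics (skewness,
entropy, co-occurrence correlation, shape) as 0 by convention. The subset
of features invariant to constant offsets is recorded in
`OFFSET_INVARIANT_FEATURES` and property-tested.

## Energy-based fusion classifier

The concatenation m = (c, o), each block min-max scaled to [0, 1] on the
training set (test values clipped), is the visible layer of a restricted
Boltzmann machine with energy

    E(x, y) = − Σᵢ tᵢxᵢ − Σₑ βₑyₑ − Σᵢₑ xᵢ θᵢₑ yₑ ,

hidden layer strictly smaller than the visible one, marginal
p(x) = Z⁻¹ Σ_y e^(−E), and data log-likelihood Σⱼ log p(xⱼ) as the
unsupervised objective. A nonstandard formulation sometimes seen in print
places the visible bias inside the activation and the interaction term;
that variant is dimensionally inconsistent with the likelihood and is kept
only behind `variant="printed"` for comparison.

Training is two-phase and fully seeded:

1. **Contrastive divergence (CD-k, default k = 1)**, learning rate 0.05,
   30 epochs, minibatch 16, real-valued visibles treated as Bernoulli
   expectations (mean-field reconstruction). Weights initialize from
   N(0, 1/√n_visible): with a much smaller scale all hidden units receive
   essentially the same CD update (the data-mean drift dominates the tiny
   random differences) and collapse onto one direction. For models with at
   most 20 total units the exact log-likelihood per epoch is recorded via
   enumeration.
2. **Supervised logistic output unit** on the hidden activations,
   full-batch gradient descent on cross-entropy plus a weak L2 penalty
   (mean CE + l2·‖w‖²/2n, l2 = 1.0 — the analogue of scikit-learn's
   C = 1). The activations are standardized for the fit and the
   standardization folded back into the stored weights, so prediction
   remains σ(w·p(h) + b). The penalty matters for honesty, not accuracy:
   an unregularized head amplifies the chance correlation between
   permuted training labels and the dominant feature direction, making a
   label-shuffle control report extreme AUCs instead of chance.

Prediction thresholds the output probability at 0.5, with ties called
positive. Exact marginals, free energy and model sampling are available
for models small enough to enumerate (≤ 20 units); larger requests raise
an explicit exact-mode error rather than silently approximating.

## Evaluation and clinical statistics

Binary metrics use the standard confusion-matrix definitions
(accuracy = (TP+TN)/total, recall = sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP)); a zero denominator yields NaN rather than an
exception. The ROC curve is the empirical curve over all thresholds and
AUC its trapezoidal area, equal to the Mann–Whitney pair statistic; it is
not clamped to [0.5, 1], so a worse-than-chance ranker is visible as such.

Grade-scale concordance uses the four-level ordinal ACL scale (0 none,
I < 50% damage, II ≥ 50%, III complete rupture). Two-modality grade tables
are compared with Pearson's chi-square without continuity correction
(a Yates flag exists); binarized diagnostic statistics treat grade 0 as
the sole negative class. Concomitant-injury positive rates compare acute
vs chronic groups with a 2×2 chi-square. The module ships the counts of a
30-patient / 60-knee cohort graded by both MRI and arthroscopy (34/10/10/6
vs 34/13/11/2 across grades III/II/I/0; 43 acute and 17 chronic injuries)
as a worked example; its chi-square is 2.44 on 3 df (p ≈ 0.49, no
modality difference).

## Desk-scale profile and problem sizes

The pipeline default is a reduced profile chosen for single-CPU runs with
the architecture unchanged and only widths shrunk: input 64 px, block
channels (4, 8, 16, 32, 32), fused channel width 32, adaptive pooling to
8×8, deep dimension 64, RBM hidden layer 24, n = 200 images per
experiment (160/40 split). Pooling to 4×4 was rejected because one pooled
cell then covers 8×8 px of the half-resolution fused map — larger than the
focal lesion — and the deep branch degrades to chance; 8×8 retains the
lesion. The deep width 64 keeps the two modalities within a factor of two
of each other (32 traditional features) so neither swamps the other in
the min-max-scaled fusion vector. The full-scale settings (input 224,
VGG16 widths, deep dimension 1026 — an intentionally odd width, kept
configurable) remain available through configuration.

## Known limitations

* The backbone is untrained unless a checkpoint is supplied; results on
  real MRI would require pretrained weights and are out of scope here.
* The traditional feature set is a documented, replaceable default; no
  claim is made that it matches any particular clinical radiomics suite.
* The label-shuffle control is a single seeded permutation; its held-out
  AUC is a draw from the permutation null, typically within ~0.2 of 0.5
  at n = 200, not a guarantee of exact chance performance.
* Chi-square p-values assume adequate expected counts; cells with zero
  expectation raise an error naming the cell instead of returning a
  misleading statistic.
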