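# Methods

This note documents the models, the synthetic phantom generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The two tasks

**Maturity classification.** Strawberries are graded D1–D4 by the fraction
of the fruit surface that has turned red: (0, 0.25], (0.25, 0.50],
(0.50, 0.75], (0.75, 1], encoded 0–3.  The boundaries are treated as
half-open intervals closed on the right, so every fraction in [0, 1] maps
to exactly one class (a fraction of exactly 0 maps to class 0).

**SSC regression.** Soluble-solids content in °Brix, the refractometric
sugar proxy, is predicted from the fruit's mean reflectance spectrum.

## Preprocessing

Order: reflectance calibration `(raw − dark)/(white − dark)` (denominator
clamped at 1e-6 so dead pixels stay finite) → crop to the closed interval
441–947 nm → Savitzky–Golay smoothing along the spectral axis (default
window 11 bands, polynomial order 3, edge windows evaluated with the fitted
polynomial, so polynomials of degree ≤ 3 pass through unchanged) → pixel-wise
area normalization (each spectrum divided by its band sum; the wavelength
grid is uniform, so the plain sum differs from a trapezoidal integral only
by a constant factor that normalization removes).  1D models consume the
mean spectrum over the fruit mask (Otsu threshold on a high-NIR band +
largest connected component); 3D models consume the normalized cube after
per-band bilinear spatial resizing.

The smoothing window is a *spectral width*, not a band count: at the
full-resolution grid (515 bands over 380–1030 nm; the unique length whose
441–947 nm crop keeps exactly 400 bands) 11 bands span ~14 nm, while on the
coarse desk-scale grid (64 bands) they span ~113 nm and visibly distort the
red edge.  Experiments that run on coarse grids should scale the window
down (the tiny test configurations use 7); the 11-band default is kept for
full-resolution spectra.

First-derivative spectra use the Savitzky–Golay derivative with the same
window, falling back to plain finite differences when a spectrum is shorter
than the window.

## Residual networks

Classification and regression share one trunk; only the dense head (4
logits vs 1 scalar) and the loss (softmax cross-entropy vs 0.5·MSE) differ.

* stem: convolution with a large kernel (7, or 7³ for cubes) and stride 2 —
  a wide receptive field near the input — followed by BN and ReLU;
* three pre-activation bottleneck stages of widths (16, 32, 64), one block
  per stage, bottleneck compression 4, stride 2 in each stage's first
  block; the shortcut is a strided 1-kernel convolution whenever channels
  or resolution change;
* final BN → ReLU → global average pooling → dropout (p = 0.3) → dense head.

Optimization is Adam at the task defaults: 1000 epochs, lr 0.01
(classification) and 1500 epochs, lr 1e-4 (regression); batch size 32 (full
batch when smaller).  In addition to the BN layers, inputs are standardized
per band with training-set statistics (toggleable,
`standardize_inputs`).  No early stopping is used, but the snapshot with
the best validation loss — parameters *and* BN running statistics, which
must be restored together — is what the trained model exposes; the
final-epoch state is kept alongside.  All randomness (initialization,
shuffling, dropout) derives from one integer seed, and the engine is pure
numpy, so training is bit-reproducible.

The engine (`berryspec.nn`) implements conv1d/conv3d as im2col + GEMM with
the column buffer reused for the weight-gradient GEMM; the input gradient
(col2im scatter) is computed only on request, so the first layer trains
without it while saliency can still backpropagate to the input.  Spectra
train in float64; cubes default to float32 for speed.

## Saliency

The contribution of an input element is `|∂y/∂x|` where `y` is the
pre-softmax logit of the true class (softmax saturation would null
gradients) or the scalar regression output, and `x` is the network input —
i.e. the standardized tensor when standardization is on.  Per-wavelength
profiles accumulate absolute gradients over the selected samples (and over
pixels, for cubes) and are normalized to sum to 1; per-pixel maps sum over
the band axis instead.  Classification saliency uses the correctly
classified test samples; regression saliency uses test samples whose
prediction error rate `|y − ŷ|/y` is at or below 5 % or 10 % (samples with
`y = 0` are excluded with a warning).  Loosening the threshold can only
grow the selected set.

## The phantom generator

Each phantom is an elliptical fruit (semi-axes 0.40·H × 0.34·W by default)
on a dark background (flat reflectance 0.02), with a contiguous red cap
grown from the apex covering the requested fraction of fruit pixels
(quantized to whole pixels, at least one when the fraction is positive; the
label is assigned from the achieved fraction).  Tissue spectra are smooth
Gaussian/sigmoid mixtures: the green endmember has the chlorophyll
absorption trough near 670 nm and a green reflectance peak near 550 nm; the
red endmember loses the trough and gains the anthocyanin-driven rise above
~600 nm.  Both blend into an *identical* NIR plateau (~0.8, with a water
dip near 970 nm) through a sigmoid red edge centred at 692 nm, so their
difference is large inside 441–700 nm and negligible above 750 nm.  Noise
is i.i.d. additive Gaussian per voxel, default sd 0.01 (1 % of full scale);
fruit spectra are floored at 1e-4 so area normalization stays defined.

Two design constraints deserve emphasis because pixel-wise area
normalization *removes brightness but preserves shape*:

* the red endmember's **visible** part is rescaled so both endmembers have
  equal integrated reflectance over 441–947 nm.  Unequal sums would rescale
  the shared NIR plateau by a class-dependent factor after normalization,
  leaking class signal into the NIR; rescaling the whole spectrum would
  instead break the identical plateau.  With the visible-part rescaling the
  class signal genuinely lives only in the visible window;
* the SSC signature added to fruit pixels is `amplitude · SSC · b(λ)` with
  `b` a **zero-integral** full sine period over 700–940 nm (default
  amplitude 0.004 reflectance per °Brix, ~5 % plateau modulation at typical
  SSC).  A same-signed bump would change each pixel's sum and smear the
  signal across all bands during normalization; a reshaping survives
  normalization exactly where it was injected.

SSC values are class-conditional normals (means 8.23, 8.57, 9.58, 10.37;
SDs 1.15, 0.8, 1.32, 1.71 °Brix for D1–D4), truncated at 0 by resampling
(negligible mass at these parameters).  `couple_ssc_to_class=False` draws
SSC from the marginal mixture independently of the label — used in
controlled saliency experiments, because with coupling the visible bands
predict SSC through ripeness and the NIR signature is no longer the only
SSC signal.

What the phantoms do **not** emulate: photorealistic fruit texture, mixed
boundary pixels, specular glare, sensor smile/keystone, wavelength-dependent
noise, or storage-time effects.  Passing tests therefore demonstrate that
the pipeline recovers the signals it is pointed at under a clean forward
model, not that the trained networks transfer to real fruit.

## Sample handling

* **Stratified repeats** (classification): per class, validation then test
  indices are drawn uniformly without replacement; the remainder trains.
  At the full study scale (204 per class, 34 + 34 held out) this gives
  136/34/34 per class; the desk-scale default holds out `n_per_class // 6`
  for each of validation and test.
* **PLS outlier screen** (regression): y is cross-val-predicted by a PLS
  regression (≤10 components, 5-fold), and samples whose centred residual
  exceeds 3 SD are flagged; the screen repeats once on the retained set.  A
  guard refuses to discard more than 20 % of the samples.
* **SPXY**: joint distance `dX/max dX + dy/max dy` (Euclidean components);
  the calibration set is grown by Kennard–Stone maximin selection starting
  from the most distant pair, ties broken toward the lowest index; the
  held-out samples are ranked by distance to the calibration set and
  assigned alternately to validation and test, keeping the two held-out
  sets distributionally balanced.  The procedure is seed-free and fully
  deterministic.

## Statistics

Overall accuracy is `100 · trace/total` of the 4×4 confusion matrix
(rows = truth).  R² is `1 − SSres/SStot`; RMSE is the root mean squared
error.  Model comparison across repeated splits uses one-way ANOVA (pooled
over the three sets and per set), judged at p < 0.01.  Grouped SSC
summaries use Tukey HSD at α = 0.05 with a compact-letter display built
from the maximal cliques of the non-significance graph, lettered in
descending order of clique mean — two groups share a letter exactly when
they are not significantly different.

## Desk-scale protocol and problem sizes

The shipped experiment defaults are a desk-scale rendition of the full
protocol, chosen so the whole pipeline (including 3D training) runs in
minutes on one CPU while preserving the architecture and optimizer
settings: 50 phantoms per class, 24×24 cubes on a 64-band grid (49 bands
after the crop), 300 epochs for the 1D classifier, 100 for the 3D
classifier, 1500 (the task default) for the regression; regression uses
144 phantoms (36 per class), mirroring the refractometer subsample size.
At these sizes the classifiers reach mid-90s test accuracy and the
regression R² triad sits around 0.77–0.99 (seed-dependent); the acceptance
script prints the exact values for a given seed.

## Known limitations

* The architecture is "compatible in spirit" with the published figures,
  not a transcription: exact kernel counts/widths beyond the configurable
  defaults are not pinned by the available description.
* The numpy engine is single-threaded per GEMM and has no GPU path;
  full-resolution 3D training (85×85×400) is supported but slow.
* Greedy maximin (SPXY) is a heuristic: its final-set minimum pairwise
  distance usually, but not provably, dominates random subsets.
* Saliency profiles are reported on the standardized input scale when
  standardization is on; per-band z-scoring amplifies near-constant bands,
  so controlled localization experiments disable it (see the generator
  section for why that is the faithful reading of "signal lives only in
  band region X").
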