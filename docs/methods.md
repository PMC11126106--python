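# Methods

## Problem and data model

The package classifies thyroid nodules as benign or malignant from
hyperspectral *blocks*: square spatial patches with full spectral depth cut
from inside surgeon-annotated nodule regions.  A case (patient) contributes
one cube of raw sensor counts — nominally 700 (x) × 600 (y) × 294 (λ) at
12-bit over 400–1000 nm, stored band-interleaved-by-pixel — plus a white
reference frame imaged off a board of known reflectance, a dark frame, and a
per-pixel label mask with codes 0 = background, 1 = normal tissue,
2 = benign nodule, 3 = malignant nodule.  A case carries exactly one nodule
diagnosis; its mask therefore contains codes {0, 1, 2} or {0, 1, 3}.

## Radiometric and spectral preprocessing

**Flat-field (whiteboard) correction.**  `SC = (S − SD)/(SW − SD) × RW`,
with `S` the raw tissue signal, `SW` the whiteboard signal, `SD` the dark
signal and `RW = 0.5` the board reflectance.  The denominator must be
strictly positive; a white frame not exceeding the dark frame anywhere is a
hard error with the offending location reported.  The form is pinned by two
sanity cases: `S = SW ⇒ SC = RW` and `S = SD ⇒ SC = 0`.

**Savitzky–Golay smoothing.**  Window 21, fifth-order polynomial, applied
along the spectral axis.  Boundary samples are taken from the polynomial
fitted to the terminal window (interpolation mode) rather than from
reflect-padding, which would bend absorption edges.  The filter is exact on
polynomials up to degree five, which the tests exploit as an oracle.

**Normalization.**  0–1 min–max rescaling.  The default scope is the whole
array (`per_block`) so that inter-band amplitude relations — which carry the
class signal — are preserved; `per_spectrum` and `per_band` scopes exist for
sensitivity studies.  A degenerate scope (max = min) maps to zeros by
convention.  Pipeline stage order is correct → smooth → normalize → trim;
the order is configurable because sources rarely pin it.

**Band trimming.**  The first and last `n_edge` bands are dropped (49 at
full scale, 294 → 196; 10 in the desk preset, 64 → 44).  The wavelength grid
always comes from the file header: the nominal instrument resolution is not
consistent with the published band counts, so it is never assumed.

**Spectral PCA.**  Pixel spectra are reduced to k = 3 components.  The fit
uses the eigendecomposition of the sample covariance; components are
variance-sorted and sign-fixed (largest-magnitude coefficient positive) so
repeated fits are bit-identical.  The projection is fitted on training-case
pixels only (at most 50 000 sampled spectra) and then frozen for validation
and test data — a leakage control, since the fitting population is not
otherwise documented.

## V3Dnet

Input: a PCA-reduced block `h × w × 3`, treated as a single-channel 3-D
volume.  Two 3-D convolutions (8 then 32 kernels) with 3 × 3 × 3 kernels,
stride 1 and zero same-padding — shape preservation is forced by the
published dataflow (two convolutions map 50×50×3 to 32 volumes of 50×50×3).
The 32 volumes are recombined into a `h × w × 96` channel image, reduced
back to 3 channels by a *PCA bridge*, per-channel standardized, and
classified by a six-block VGG-style head: five convolutional blocks of
(2,2,2,3,3) 3×3 convolutions with ReLU and 2×2 max pooling between blocks
(channel widths 64/128/256/512/512 by default), an adaptive average pool, and
three fully connected layers ending in a two-class softmax.  The (2,2,2,3,3)
block layout is kept as published even though canonical VGG16 is (2,2,3,3,3).
The adaptive pool realizes "size correction": any block size (20/40/50/80)
feeds the same fully connected head without 224×224 upsampling artefacts.

**PCA bridge.**  Fitted per block over the `h·w` pixel feature vectors, with
the same deterministic sign convention as the spectral PCA.  During
backpropagation the projection (mean and loading rows) is treated as a
constant linear map (straight-through): differentiating through
eigenvectors is numerically fragile and contributes no trainable
parameters.  A `global` mode that applies one frozen projection fitted on
training features is available behind a flag.  The per-channel standardizer
likewise treats its mean and standard deviation as constants in the
backward pass.

**Baselines.**  `cnn1d` (two 1-D convolutions on the spatially pooled block
spectrum), `cnn2d` (two 2-D convolutions on the PCA image), `cnn3d` (the
two-stage 3-D extractor with a dense head), and `vgg16` (the six-block head
alone).  All share the block interface and softmax contract.

All layers are numpy implementations with explicit backward passes;
convolutions run as im2col matrix products in float32.  Gradients are
verified against central differences in the unit tests.  Dropout is not
used (undocumented in the source architecture; default off).

## Training and evaluation

Class-weighted softmax cross-entropy with weights inversely proportional to
class counts and normalized to mean 1; the weighted loss satisfies the
count/weight duality (doubling a class's multiplicity while halving its
weight leaves the loss unchanged), which is tested.  Optimization is SGD
with optional classical momentum, optional multiplicative per-epoch
learning-rate decay and optional global gradient-norm clipping.  The
full-scale recipe is lr 0.001, batch 64, 150 epochs; the published
alternative regime (batch 32, 300 iterations) is expressible through the
same configuration.  "Iterations" is read as epochs.  Training always runs
the full epoch budget — no early stopping — but the checkpoint with the
best validation accuracy is kept alongside the final one, and the
experiment drivers evaluate that checkpoint (model selection on validation
data only).

Train/validation case overlap is a hard error.  Splits are case-level and
stratified by diagnosis: per-stratum round-to-nearest counts adjusted to
the exact global target (a 150-case cohort of 80 malignant / 70 benign
yields 105 train / 45 test with 15 of the 105 flagged validation).
Ten-fold cross-validation assigns cases to folds round-robin per stratum.

Metrics (malignant positive): ACC, SEN, PRE, F1 and Type-I error =
FP/(FP+TN), reported as percentages at two decimals, rounding half away
from zero.  F1 is computed from the two-decimal SEN and PRE, matching the
precision at which those are reported.  Type-I follows a
round-to-three-then-truncate-to-two display convention — the only
deterministic two-decimal rule consistent with every published Type-I
value.  A metric with a zero denominator is returned as undefined (`None`),
never as a silent zero.  Two of the published Type-I cells (3D CNN and VGG)
are inconsistent with their own confusion rows — the printed 3D CNN value
equals the one derived from the VGG row, a column shift — and the 20×20 and
40×40 rows of the block-size table disagree with their printed counts;
these cells are treated as errata and excluded from comparisons.

Test-time ordered-crop averaging classifies a region by enumerating
row-major strided crops, averaging their softmax vectors and taking the
argmax of the mean.

## Synthetic data generator

The generator emulates the acquisition phenomenologically, not
biophysically (no hemoglobin absorption model):

* **Endmembers.**  Per-class reflectance curves are sums of a few Gaussians
  over the wavelength grid, scaled into [0.05, 0.45] — below the 0.5 board
  reflectance, so corrected spectra stay inside the calibrated range
  [0, RW·(1+5·noise sd)].  The malignant curve is a rotation of the benign
  one within the spectral simplex, bisected until the realized spectral
  angle is within 10% of the requested separation; separation 0 gives
  identical curves.  One endmember library is shared across a cohort.
* **Scene.**  A background border, a normal-tissue interior, and 1–2 nodule
  blobs per case — discs with smooth random harmonic boundary perturbation
  (roughness 0.15), radius 35–55 px at desk scale — which exercises purity
  filtering on irregular boundaries.
* **Radiometry.**  A smooth low-order polynomial illumination field
  (±15%) times a smooth lamp spectrum, a dark level of 100 counts with 2
  counts of read noise, a signal scale of 3600 counts, and 12-bit
  quantization.  Flat-field correction of a generated cube recovers each
  pixel's endmember up to jitter, noise and one quantization step (~3·10⁻⁴
  in reflectance units), which the tests assert.
* **Variability.**  Within-class texture is a spatially smooth
  multiplicative jitter field (Gaussian-filtered white noise, correlation
  length 8 px, sd 0.05) — tissue texture is spatially correlated, and
  spatial structure is what the 3-D convolutions consume — plus i.i.d.
  additive band noise (sd 0.02 by default).

The desk preset (160 × 160 × 64 cubes, 8 cases per class) keeps the full
pipeline under a few minutes on one CPU; the full-scale geometry is
available for stress tests.  What passing desk-scale tests show is that the
pipeline recovers planted spectral class structure and reports chance when
none exists; they do not certify clinical accuracy, which depends on real
tissue variability, annotation quality and scanner characteristics absent
from this model.

## Desk-scale recovery experiment

`pipeline.run_synthetic_experiment` generates an 8+8-case desk cohort,
splits by case (stratified 0.7 train fraction, 1/7 of train as validation),
preprocesses with `n_edge=10`, cuts 20×20 blocks — training blocks with
stride 10 (overlapping crops, the augmentation-rich regime; evaluation
tiles remain non-overlapping at stride 20) — fits the spectral PCA on
training pixels, and trains a scaled V3Dnet (8/16 conv kernels, VGG widths
8/16/16/32/32, FC 64/32) for 30 epochs with lr 0.05, momentum 0.9, per-epoch
decay 0.90, gradient-norm clip 25 and batch 32.  The best-validation
checkpoint is evaluated on held-out-case blocks.  At separation 0.3 rad the
held-out block accuracy is high (≥ 0.9); at separation 0 it is chance on
average.  Because test blocks are correlated within the ~5 held-out cases,
single-run accuracy at separation 0 has case-level variance; the chance
assertion therefore averages three seeds.

## Numerical and design choices

* 12-bit counts are stored in unsigned 16-bit words; cubes are exchanged as
  raw BIP binary with a minimal ENVI-compatible ASCII header (BIL/BSQ are
  read and converted); masks as 8-bit PNG; cases as HDF5 containers.
* 0-based (row, col) indexing, row-major, everywhere; block origins are
  top-left corners.
* Purity default 1.0: a block must lie entirely inside one nodule, since
  edges, background and blood measurably hurt classification.  Stride
  defaults to the block size (non-overlapping); smaller strides are an
  explicit opt-in.
* All randomness flows through explicit integer seeds and
  `numpy.random.default_rng`; no global random state.  Same seed, data and
  configuration ⇒ identical parameter trajectories on one worker.
* Convolution weights use He initialization; biases start at zero.
* Ties in the sign convention (two coefficients of equal magnitude) resolve
  to the first index; ties in block purity between codes resolve to benign.

## Known limitations

* The generator's spectra are phenomenological; no scatter correction,
  SNV/MSC or wavelet features are implemented.
* The PCA bridge's straight-through gradient ignores the dependence of the
  projection on upstream activations; training signals through the bridge
  are therefore approximate.
* Published real-data accuracies require the clinical dataset and
  full-scale training and are out of scope here; the package reproduces the
  metric arithmetic of the published tables and the synthetic recovery
  behaviour, not the clinical numbers.
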