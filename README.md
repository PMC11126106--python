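# thyrospec

Block-based benign/malignant classification of thyroid nodules from medical
hyperspectral images.

Resected thyroid tissue imaged by a visible/near-infrared line-scanning
hyperspectral camera yields cubes of roughly 700 × 600 pixels × 294 bands at
12-bit depth, with a per-case white-reference (whiteboard) frame, a dark
frame and a surgeon-annotated label mask (background / normal tissue /
benign nodule / malignant nodule).  Rather than segmenting pixels, the
pipeline classifies *blocks* — square spatial patches with full spectral
depth cut from inside annotated nodules — which is closer to the
intraoperative question ("is this nodule benign or malignant?") and
insulates the classifier from tissue edges, background and blood stains.

## Pipeline

1. **Radiometric calibration** — flat-field (whiteboard) correction
   `SC = (S − SD)/(SW − SD) × RW` with a reference board of known
   reflectance `RW = 0.5`, converting raw counts to reflectance.
2. **Spectral conditioning** — Savitzky–Golay smoothing along the spectral
   axis (window 21, fifth-order polynomial), 0–1 min–max normalization, and
   trimming of the noisy edge bands (294 → 196 at full scale).
3. **Block construction** — non-overlapping tiles (20/40/50/80 px) kept only
   when a single nodule class covers the whole footprint; splits are made at
   the *case* (patient) level, stratified by diagnosis, so no patient leaks
   across train/validation/test.
4. **Spectral PCA** — pixel spectra are reduced to k = 3 principal
   components, fitted on training-case pixels only.
5. **V3Dnet** — two shape-preserving 3-D convolutions (8 then 32 kernels of
   3×3×3) extract spatio-spectral features; the 32 feature volumes are
   recombined into a 96-channel image; a per-block PCA bridge reduces the
   channels back to 3; a six-block VGG-style head (2,2,2,3,3 convolutions +
   3 fully connected layers, ReLU, 2×2 max pooling) ends in a two-class
   softmax.  For the default 50×50 block the shape chain is
   `50×50×196 → 50×50×3 → 32@50×50×3 → 50×50×96 → 50×50×3 → 2`.
6. **Training/evaluation** — class-weighted cross-entropy (weights inverse
   to class counts), SGD, per-epoch shuffling, optional test-time
   ordered-crop averaging, and confusion-matrix metrics with malignant as
   the positive class:

   ACC = (TP+TN)/N, SEN = TP/(TP+FN), PRE = TP/(TP+FP),
   F1 = 2·PRE·SEN/(PRE+SEN), Type-I error = FP/(FP+TN).

The network layers (3-D/2-D/1-D convolutions, pooling, PCA bridge, dense
head) and their backpropagation are implemented directly in numpy with
im2col matrix products; the models here are small enough that CPU training
takes seconds to minutes.

A synthetic-case generator (`thyrospec.synthgen`) emulates the acquisition:
smooth per-class endmember reflectance curves with a controllable
benign-vs-malignant spectral-angle separation, spatially smooth tissue
texture, irregular nodule blobs in a normal-tissue background, a polynomial
illumination field, reference frames, sensor noise and 12-bit quantization.
Every pipeline stage is therefore testable without the clinical dataset.

## Worked example

```python
from thyrospec.pipeline import run_synthetic_experiment

res = run_synthetic_experiment(separation=0.3, noise_sd=0.02,
                               epochs=30, seed=7)
print(res["n_blocks"])       # {'train': 355, 'val': 20, 'test': 63}
print(res["metrics"])        # {'ACC': 100.0, 'SEN': 100.0, 'PRE': 100.0,
                             #  'F1': 100.0, 'TypeI': 0.0}
print(res["test_accuracy"])  # 1.0
```

This generates a desk-scale cohort (16 cases of 160 × 160 × 64 cubes, benign
and malignant endmembers separated by a 0.3 rad spectral angle, noise sd
0.02), trains a scaled V3Dnet (20 × 20 blocks, 8/16 conv kernels) for 30
epochs and evaluates it on blocks from held-out cases: the spectral class
structure planted by the generator is recovered with high accuracy
(held-out block accuracies around 0.88-1.00 across seeds, 0.96 on average;
this seed classifies every test block correctly).  At
`separation=0.0` the two classes are spectrally identical and accuracy
drops to chance — the pipeline finds signal exactly when signal exists.

The same flow is scriptable from the shell:

```sh
thyrospec simulate --out cases/ --n-benign 8 --n-malignant 8 --seed 1
thyrospec blocks --cases cases/ --out blocks/ --size 20 --n-edge 10 --seed 1
thyrospec train --data blocks/ --out run/ --epochs 30 --seed 1
thyrospec evaluate --checkpoint run/model.npz --data blocks/test_blocks.h5
```

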