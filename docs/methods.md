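# Methods

This note records the modelling choices behind `histodense`: what each stage
assumes, which parameters matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Calibration and density calculus

Microns-per-pixel is the sensor pixel pitch divided by the total visual
magnification, `mpp = pps / m`, with `pps = 6.5 µm` by default (a common
1/3-inch CCD pitch) and square pixels assumed (`mpp_x = mpp_y`). Patch
dimensions convert linearly (`w_x = w_p·mpp`), areas quadratically, and
µm² → mm² uses the factor 10⁻⁶ — the physically correct conversion, which
every consistent reference value reproduces. Nuclei density is
`a_d = n / a_mms` in nuclei per mm². All arithmetic is exact; rounding
happens only when formatting. Relay-lens factors are deliberately folded
into the nominal magnification: the calculus follows the published
per-magnification mpp table literally (6.5/40 = 0.1625 etc.).

Note one internal inconsistency in the reference geometry table we
reproduce: its 100× row squares the *rounded* patch width (14.6² = 213.16)
whereas the exact width is 224·0.065 = 14.56 (area 211.9936). We always
compute exactly and compare other rows at their printed precision; the 100×
area cell is not asserted.

## Patch tiling

Two deterministic tilings of a `W×H` field with patch size `P`:

* **grid6** — 3 evenly spaced columns × 2 rows, first tile at the origin,
  last flush with the far edge (700×460/224 → x ∈ {0, 238, 476},
  y ∈ {0, 236}). This is the mode whose per-image count (6) reproduces the
  ×6-consistent corpus bookkeeping. It leaves two thin uncovered bands
  (x ∈ [224, 238) ∪ [462, 476), y ∈ [224, 236)).
* **cover** — the minimal evenly spaced grid whose half-open footprints
  cover every pixel (4×3 = 12 tiles for 700×460/224), verified against a
  brute-force coverage oracle for randomized geometries.

Offsets are 0-based, row-major; patches are exact pixel copies (no
resampling). Neither mode filters background; none is applied upstream
either.

## Stain model

Optical density `OD_c = −log(I_c / I₀)` is modelled as a linear mixture of
unit-norm stain absorption vectors; defaults are the canonical H&E pair
H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11) with an orthogonal residual
completing the basis, `I₀ = 255`. Concentrations are the exact solution of
the 3×3 system, clipped at zero. Intensities are clipped to `[ε, I₀]` with
ε = 1 intensity unit before the log — this guards `log 0` exactly like an
additive ε for 8-bit data while keeping the deconvolution an exact inverse
of the Beer–Lambert renderer on float inputs (round-trip error is machine
epsilon on noise-free renders; the test bound is 10⁻⁶ OD). The
stain-removed structure image reconstructs from hematoxylin alone,
`I₀·exp(−c_H)`, leaving nuclei dark on a uniform background.

Gaussian denoising uses reflective borders; σ defaults to 1 px (the value
is not dictated by anything physical — it suppresses shot-like noise
without erasing small nuclei at these scales) and σ = 0 is a strict
identity. The segmenter consumes the denoised RGB patch by default; a
config switch feeds the hematoxylin channel instead.

Training-time augmentation (rotation ±20°, zoom ±10%, shear 10%, optional
flips, intensity rescale) is split into a *range* object and a concrete
*applied* sample so that every stochastic draw is seeded and replayable.

## Segmentation network

A 5-level U-Net: each encoder stage is two 3×3 stride-1 convolutions with
ReLU; the four downsamplings between stages are 3×3 stride-2 max-pools with
'same' padding. Taking the stated stage strides and pools literally would
shrink a 224-px input past its bottleneck, so stride-1 convolutions with
pooled downsampling is the consistent reading; pooling padding is 'same'.
The decoder mirrors with nearest ×2 up-sampling. Skip connections pass
through additive attention gates (1×1 projections of skip and gating
signals, sum, ReLU, 1×1 projection, sigmoid; the resulting per-pixel weight
in [0, 1] multiplies the skip features — so gated activations are always
elementwise bounded by the skip activations). A 1×1 convolution emits
logits; the sigmoid is fused into the loss for numerical stability.

Defaults follow the reference training setup: encoder filters
(16, 32, 64, 128, 256), Adam, learning rate 10⁻⁴, 50 epochs, batch 16,
binary cross-entropy. `width_scale` multiplies all stage widths for
desk-scale runs. Dice between two empty masks is defined as 1.0 (0/0 in
the set formula; perfect agreement is the standard convention).
K-fold evaluation partitions a seeded permutation into k folds and reports
per-fold pixel metrics.

The Otsu baseline thresholds the hematoxylin concentration map globally
(nuclei bright); polarity flips for stain-removed grayscale input. A
constant image has no threshold and yields an empty mask with a warning.

## Numpy layer engine

No deep-learning framework is part of the runtime: `histodense.nnet`
implements the exact layer vocabulary the two network families need
(im2col convolution, depthwise convolution, max-pooling with −∞ padding,
nearest up-sampling, batch normalisation, inverted dropout, dense layers,
Adam/SGD/RMSProp, fused sigmoid-BCE / softmax-CCE losses) in float64 with
hand-written backward passes. Every layer's backward is verified against
central finite differences in the test suite (tolerance 10⁻⁶). Single-
threaded float64 numpy makes identical seeds produce bit-identical
training histories.

One engine-level subtlety: with few small batches, exponentially averaged
batch-norm statistics lag the final weights badly enough to corrupt
inference. After every epoch the running statistics are therefore replaced
by the exact moments of each normalisation layer's input along the
inference path ("precise BatchNorm" re-estimation over the training set).

## Stratification

Per-patch densities (connected components of the binary mask with area ≥
`min_area` = 10 px at 8-connectivity) are thresholded at the cumulative
30:30:40 fractions of the maximum observed density. The ratio text appears
in two variants in the source material (30:30:40 and 30:40:40, the latter
summing to 110); 30:30:40 is the default and the ratio is configurable. A
quantile basis (30th/60th percentile, linear interpolation) is offered
because per-bin counts in the reference tables are not derivable from
either reading without the original data. Ties close the lower bin
(`d = t_low` → LD). Thresholds are computed per magnification by default.
Benign patches bypass density entirely and are copied into all three bins.
The 70/15/15 split is stratified per (bin, class) with its own seeded
shuffle; floor rounding sends residues to training.

## Classifiers

* **SCNN** — six 3×3 convolutions (16, 32, 64, 128, 256, 256 — the source
  lists "six" layers but only five sizes; the sixth repeats 256), three 2×2
  max-pools, two batch-norms, three dropout layers at 0.30, two ReLU dense
  layers, 2-way softmax.
* **DCNN** — MobileNet-v1-shaped: stride-2 stem convolution (ReLU, no
  norm), then 13 depthwise-separable blocks (depthwise 3×3 + pointwise 1×1,
  channels 64→1024, stride-2 depthwise at blocks 2, 4, 6 and 12 preceded by
  explicit zero-padding). That reading — not the stated "fourteen"
  depthwise layers — is the one consistent with the stated inventory of 13
  pointwise layers, 26 batch-norms, 27 ReLUs and 4 zero-pads. ImageNet
  MobileNet weights are an optional external input; nothing depends on
  them.

Both train with categorical cross-entropy and the schedule
`lr(e) = max(lr₀·0.8ᵉ, floor)` (defaults lr₀ = 10⁻⁵/10⁻⁴ for SCNN/DCNN,
floor 10⁻⁸), early stopping on validation loss (min_delta 0.01/0.001,
patience 5/10). Specificity is the standard `TN/(TN+FP)`; the source's
printed specificity formula (`TP/(FP+FN)`) is not a specificity and is
reported only behind a debug flag. The "AUC" of the printed metric suite is
balanced accuracy `½(TPR+TNR)`; the threshold-free Mann–Whitney ROC AUC is
reported alongside, clearly labelled. Zero-denominator metrics are reported
as undefined, never as zero. One model is trained per (bin, magnification),
matching the structure of the reference report tables.

## Synthetic data

Scenes are 700×460 (or any requested size) fields of elliptical nuclei with
low-order radial-harmonic boundary irregularity, placed by rejection
sampling: a candidate is accepted when its centre distance to every placed
nucleus exceeds `(1 − allowance)·(r_max,i + r_max,j)`. Negative allowances
enforce a separation margin (used for the "well-separated" training
corpora); positive allowances permit partial overlap so the segmenter's
hard case is exercisable. Nuclei carry hematoxylin concentrations, the
background a low-frequency eosin texture; rendering is Beer–Lambert through
the preprocessing module's stain vectors, plus optional Gaussian pixel
noise (default sd 2 intensity units) and 8-bit quantisation. The unquantised
float render is kept alongside for exact deconvolution checks.

Default class contrast — benign-like: 30–60 round (eccentricity ≤ 0.3),
size-uniform (r 7–11 px), non-overlapping nuclei per field; malignant-like:
120–240 pleomorphic nuclei (eccentricity 0.4–0.8, r 4–13 px, irregular
boundaries, 10% overlap allowance). Patch-scale variants (64×64: 3–6 vs
12–20 nuclei) keep the same contrast at classifier-input size. These mimic
the qualitative benign/malignant morphology difference the method exploits;
they do **not** reproduce the colour statistics, texture, artifacts or
morphological diversity of real stained tissue. Passing tests therefore
demonstrate that the pipeline's machinery is correct and learnable-from,
not that real-data headline performance transfers.

## Desk-scale study conditions

Training checks run on 1 CPU in minutes, so they use deliberately reduced
problem sizes, chosen once:

* Segmenter: 64 patches of 64×64 px ("easy" corpus: 3–6 well-separated
  dark nuclei, separation margin 0.2), width_scale 0.25, ≤ 15 epochs,
  batch 8, learning rate 10⁻² (tens of optimizer steps on a width-scaled
  net need a desk-scale step size; the paper-scale default stays 10⁻⁴).
  Property: validation Dice ≥ 0.90, near-empty masks on nucleus-free
  controls, held-out instance counts within 10% on ≥ 90% of patches.
* Classifier: 150 patch-scale scenes (104/22/24 split), width_scale 0.25
  SCNN at 64×64 input, ≤ 20 epochs, lr 10⁻³ with decay 0.9. Property: test
  accuracy ≥ 0.95.
* Stratification: 60 malignant 224-px patches with generated counts 5–10 /
  25–35 / 60–80; ground-truth-mask counting must recover the intended bin
  for ≥ 95%.

Headline full-corpus numbers (99.9%-range Dice/accuracy) require the
external image collection and GPU-scale training and are explicitly out of
scope here.

## Numerical and degenerate-input choices

* Thresholded masks use `probability ≥ threshold`, so threshold 0 is
  all-foreground and 1+ε all-background.
* Inputs whose spatial size is not divisible by 16 are reflect-padded for
  prediction and cropped back; training inputs must be divisible.
* Even-grid tile offsets round to integers; duplicate offsets collapse
  (a field equal to the patch size yields a single tile).
* Empty density lists, empty datasets, single-class training sets, fraction
  vectors not summing to 1, non-positive calibration constants and singular
  stain matrices are rejected with explicit errors.
* CSV/JSON are the only manifest formats; model checkpoints are `.npz`
  arrays with a JSON sidecar carrying the config hash and seed.

## Known limitations

* The segmenter does not split touching nuclei (no watershed/boundary
  post-processing); counts on overlapping clusters undercount.
* The synthetic generator's realism limits: no staining variability across
  slides, no artifacts, no tissue architecture.
* Per-magnification appearance differences are emulated only by folder
  structure, not by rescaled morphology.
* The numpy engine is CPU-bound and float64; paper-scale training is out
  of its intended envelope.
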