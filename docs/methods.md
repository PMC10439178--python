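# Methods

`skinaudit` quantifies the representation of dark skin tones (Fitzpatrick
V–VI) in the figures of educational documents. The pipeline has five
stages — figure extraction, skin-image detection, skin-pixel segmentation,
tone classification, and aggregation — each usable on its own.

## Figure extraction

Documents are either PDFs or directories of raster images (one page per
file). For PDFs, only embedded raster XObjects are extracted; vector
graphics and text are ignored, and no OCR or page rendering is performed.
Each extracted figure carries its provenance: 1-based page number and a
bounding box in page points with a **top-left origin** (native PDF is
bottom-left; we flip using the page's MediaBox because most viewers and
imaging tools index from the top). Grayscale and CMYK images are converted
to sRGB on extraction, since every later stage assumes 3-channel sRGB.
Images placed twice are kept as distinct records: each placement is a
separate occurrence in the material being audited. Figures smaller than
`min_dim` (default 100 px) in either dimension are dropped as decorations.

PDF reading/writing is a small in-repo module scoped to this task
(FlateDecode and baseline-JPEG image XObjects, classic cross-reference
structure). Encrypted files are rejected with a clear error; unsupported
XObjects are skipped rather than failing the document.

## Skin-image detection

Each figure is summarized by a 38-dimensional descriptor:

* **Global HOG (32 values).** Central-difference gradients
  `Gx(r,c) = I(r,c+1) − I(r,c−1)`, `Gy(r,c) = I(r+1,c) − I(r−1,c)` of the
  scalar intensity image; per-pixel direction `θ = arctan(Gy/Gx)` on
  `(−π/2, π/2]` and magnitude `M = √(Gx² + Gy²)`. Every interior pixel
  adds `M` to the nearest of 32 equal-width direction bins; the histogram
  is L1-normalized when total magnitude is positive. This is a single
  global histogram (no cells or block normalization).
* **CIELAB statistics (6 values).** Mean and population standard deviation
  of L\*, a\*, b\* under a D65 2° observer.

The intensity channel for gradients is Rec.601 luma
(0.299 R + 0.587 G + 0.114 B) of the raw 8-bit values. A channel linear in
RGB makes the HOG exactly invariant to adding a constant to all pixel
values and gives a grayscale ramp a gradient of exactly 2 — properties a
nonlinear channel such as CIELAB L\* would only satisfy approximately.

Two classifiers are provided: a ν-SVM with RBF kernel (ν = 0.01,
γ = 0.05, chosen small to limit support-vector count and overfitting;
scores are mapped to probabilities by a logistic fit on training decision
values) and gradient-boosted trees whose depth / tree count / learning
rate are picked from a small grid by internal 3-fold AUROC. Evaluation is
stratified k-fold (default 5) reporting AUROC and F1, skin positive, with
the hard-label threshold fixed at 0.5.

## Skin-pixel segmentation

A pixel is a skin candidate when it lies inside published skin loci in
**both** HSV and YCbCr: H ∈ [0°, 50°], S ∈ [0.15, 0.70], V ≥ 0.25, and
Cb ∈ [77, 127], Cr ∈ [133, 173] (8-bit BT.601). All five intervals are
configuration keys. The candidate mask is refined in a fixed order:

1. morphological opening then closing (disk radius 3 px each) to clear
   speckle and close pinholes;
2. removal of components below 0.5 % of the image's pixels;
3. region growing: neighbors within CIELAB ΔE ≤ 12 of the seed
   component's mean color are admitted (component means are frozen at the
   start so regions cannot drift);
4. a watershed on the luminance-gradient image, seeded from eroded
   component cores, whose one-pixel ridge lines split merged regions;
5. a final small-component sweep, so no output component is below the
   minimum area.

The procedure is deterministic and idempotent on clean masks. Lesional
skin is **not** excluded: a diseased-skin photograph counts as skin.
Evaluation uses pixel-fraction conventions — TP/TN/FP/FN as fractions of
all pixels (summing to 1, so accuracy = TP + TN) — plus the Jaccard
index; a batch helper returns per-image metrics and their mean (the
pooled and per-image-averaged views can differ, so both are reachable).

## Tone classification

The endpoint is binary: Fitzpatrick I–IV (light) vs V–VI (dark), dark
positive. Three routes:

* **ITA table.** The individual typology angle
  `ITA = arctan((L − 50)/b)·180/π` is averaged over the mask and looked
  up in a configurable table (defaults: I > 55°, II 41–55°, III 28–41°,
  IV 10–28°, V −30–10°, VI ≤ −30°; boundary values go to the lighter
  type). `b = 0` resolves to ±90° by the sign of L − 50. Training-free
  but lighting-sensitive.
* **Ensembles** on a 38-dim tone descriptor (masked-region HOG, masked
  μ/σ of L\* and b\*, and the mean and standard deviation of per-pixel
  ITA): random forest, balanced random forest (realized as a
  `balanced_subsample`-weighted random forest), extremely randomized
  trees, AdaBoost, gradient boosting. The ITA summary is configurable to
  mean-only (37-dim vector).
* **CNN.** An 18-layer residual network — 7×7/2 stem, four stages of two
  basic blocks (64/128/256/512 channels), global average pooling, 2-way
  head — implemented directly on NumPy with explicit backpropagation
  (convolutions as im2col matrix products). With a 1000-way head it has
  11,689,512 trainable parameters; the 2-class head gives 11,177,538.
  Input is the masked image (non-skin pixels zeroed) resized to a square
  network input; fine-tuning is mini-batch SGD (momentum 0.9) on
  class-weighted cross-entropy with the learning rate decaying linearly
  from 10⁻³ to 0 across epochs, batch size 32. After training, batch-norm
  running statistics are recomputed exactly over the training set (the
  `update_bn` idea from stochastic weight averaging): after short
  fine-tunes the exponential estimates lag the final weights, which
  otherwise degrades inference-mode predictions. Pretrained backbone
  weights can be loaded from a file when available; initialization is
  otherwise random and seeded. The weighted cross-entropy reduction is
  `Σ wᵧ·ce / Σ wᵧ`, which collapses to the plain mean under equal
  weights.

Metrics are class-frequency weighted (accuracy, precision, recall, F1)
plus threshold-free AUROC; with a single true class the AUROC is reported
as NaN rather than a fabricated value. The split helper produces
stratified 70/10/20 train/validation/test partitions.

## Aggregation and reporting

Per document: `n_images_total = n_skin + n_nonskin` and
`n_skin = n_dark + n_light + n_excluded`, where excluded images are
detected skin images whose segmentation mask came back empty — they are
removed from the tone denominator and reported separately rather than
guessed at. The headline proportion is `n_dark / (n_dark + n_light)`,
null when no image could be tone-classified. Reports render to JSON
(lossless round-trip), Markdown and per-image CSV; every row keeps its
(page, bbox) provenance.

## Synthetic data

The generator produces the fixtures every stage is tested on:

* **Skin images**: a skin-colored ellipse with per-pixel CIELAB jitter
  (σ = 2), optional clothing strip and optional darker lesion blob
  (kept inside the truth mask, since segmentation does not exclude
  lesions), on one of four non-skin backgrounds. Light-class colors are
  drawn from L\* ∈ U(60, 78), b\* ∈ U(12, 22) and rejection-resampled to
  ITA > 10°; dark-class from L\* ∈ U(28, 45), b\* ∈ U(4, 14) to
  ITA ≤ −30°. The classes are therefore ITA-separable by construction
  (gap ≥ 40°), which makes tone-recovery tests well-posed.
* **Non-skin figures**: line charts, text blocks, and histology-like
  pink textures — the figure types a document auditor most often has to
  reject.
* **Documents**: PDFs placing a generated dataset four images per page at
  recorded bounding boxes, with a truth manifest (page, bbox, labels)
  aligned by placement order.

Defaults: 128×128 px images (above the 100-px extraction filter), 60 %
skin images, 30 % dark among skin. The dark share is set well above the
roughly 10 % observed in real teaching materials so that fixture-scale
training sets contain enough minority examples; the imbalance mechanisms
(weighted loss, balanced forests) are exercised separately with a 9:1
fixture. Problem sizes in the tests (200 images, 5 fine-tuning epochs,
32×32 CNN input) are chosen so the whole suite runs in about a minute of
CPU while every stage still has headroom over its thresholds.

What the generator does **not** emulate: photographic texture, lighting
and camera color-balance variation, multi-person plates, panel figures,
or skin colors outside the two sampled loci. Passing tests therefore
demonstrate correctness of the machinery and recoverability under
controlled conditions, not field accuracy on real textbooks.

## Numerical choices and degenerate inputs

* Direction-bin assignment: nearest of the equal-width bin centers on
  `(−π/2, π/2]`, boundary ties to the lower-index bin; `Gx = 0, Gy ≠ 0`
  maps to +π/2 (same orientation as −π/2); zero-gradient pixels carry
  zero weight.
* A constant image yields an all-zero HOG (no mass to normalize).
* Standard deviations are population (divide by N) throughout —
  deterministic and mask-size independent.
* Masked regions thinner than 3 px in either direction yield a zero HOG
  block in the tone descriptor (no interior pixels for central
  differences).
* Empty segmentation masks raise a typed error ("no skin detected") that
  the reporting layer converts into exclusion, never a silent zero.
* All stochastic components (generators, classifiers, SGD) take explicit
  seeds; identical seeds give bit-identical outputs.

## Known limitations

* Very dark skin sits near the edge of the published HSV/YCbCr loci;
  occasionally a dark-skin image produces an empty mask and is excluded,
  which biases the measured dark share downward. The report surfaces
  `n_excluded` so this is visible rather than silent. This mirrors a
  genuine weakness of rule-based skin segmentation on dark tones.
* The PDF module covers the raster-image subset of PDF only; exotic
  encodings (JBIG2, JPX, predictor-filtered Flate) are skipped.
* Tone classification is binary by design; the six-way Fitzpatrick
  index is exposed only through the ITA route.
* `.pptx`/`.docx` ingestion is a format hook without a parser.
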