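# Methods

## Problem setting

A line-scan VNIR hyperspectral imager records a stainless-steel plate
carrying dried droplets of vegetable juice at six dilution levels
(100%, 20%, 10%, 5%, 2%, 1% by volume; classes *Hundred*, *Twenty*, *Ten*,
*Five*, *Two*, *One*) with fifteen repeats per level — 90 droplets per
plate — plus the bare-steel background class *BG*. The cube has two spatial
axes and 128 spectral bands spanning 400–1000 nm. The analysis recovers
droplet regions, extracts per-pixel reflectance spectra, and classifies
each spectrum into one of the seven classes.

## Reflectance calibration

Raw counts are converted band-wise to reflectance,
`R = (I − D) / (W − D)`. Dark and white references may be full cubes or
per-band frames; full cubes are collapsed to per-band 2-D frames by
averaging over scan lines before division, the usual treatment for
line-scan references (per-pixel references are equally accepted — the
quantity is broadcastable). Reflectance is clipped to `[0, 2]` by default:
specular metal pixels legitimately exceed 1, and the number of clipped
values is recorded rather than silently discarded. Calibration is
scale-invariant: multiplying raw, dark and white by a common positive
constant leaves `R` unchanged.

ENVI I/O uses BSQ interleave, 32-bit float for reflectance and 16-bit
unsigned integers for raw counts, with the wavelength list carried in the
header. Round-trips are bit-exact for the stored datatype.

## Synthetic plate forward model

No measured hypercube is distributed with this problem, so the simulator
is a first-class module and defines the study conditions for every test.

* **Background.** Bare steel has a smooth, spatially constant profile
  `R_bg(λ)` (default 0.62 at 700 nm with a mild +0.06 slope across the
  range), kept within (0, 1].
* **Residue absorption.** A dried droplet attenuates the background as
  `R(λ; c) = R_bg(λ) · exp(−τ(c) · A(λ))`, where `A(λ)` is a unit-peak sum
  of Gaussian features centered at 625, 720, 785 and 860 nm (widths 28–34
  nm) — the characteristic pigment/overtone region of vegetable residues —
  and `τ(c)` is the effective optical depth of the deposit.
* **Concentration response.** `τ(c) = k·c^p` with contrast gain `k = 2`
  and exponent `p = 0.2`. The sublinear (saturating) exponent reflects how
  dried-film optical density responds to solution concentration: diluting
  an already dilute solution thins the deposit much less than
  proportionally. It is also what makes the plate segmentable: with a
  linear response the 1–2% droplets would sit within the background noise
  of any global threshold and no mask method could recover the designed
  droplet count, while all mean spectra would still be distinct — a regime
  the dilution experiment clearly did not occupy. Reflectance remains
  strictly decreasing in `c` at every feature wavelength.
* **Drying ring.** Each droplet carries an outer rim (2 px) whose optical
  depth is scaled by 1.4, mimicking coffee-ring deposits and making
  segmentation boundaries non-trivial. Note that rims deliberately blur
  class boundaries for per-pixel classification: the rim of a dilute
  droplet can match the interior of a stronger one. Fixtures that probe
  pure class separability therefore disable the rim (`rim_gain = 1`).
* **Acquisition.** Raw counts are `D + (W − D)·R` with dark level `D = 100`
  and white level `W = 3000`, plus i.i.d. Gaussian sensor noise
  (`σ = 25` counts ≈ 0.9% reflectance by default; 0 gives exact
  invertibility). Dark and white cubes carry the same noise model. Striping
  and other structured line-scan artifacts are not modeled.
* **Geometry.** Default raster 256 × 220 px (a scaled-down plate so the
  full simulate–segment–classify chain runs in seconds; the native
  1000 × 1004 size is a config away), 15 rows × 6 dilution columns,
  radius-6 droplets on a 16 × 32 px grid. Layouts validate disjointness
  and containment. The "two replicates" of the physical protocol are
  modeled as additional plates from further seeds rather than a second
  on-plate column block, matching the 90 = 6 × 15 droplet count.

What passing tests on this simulator do **not** show: robustness to real
EMCCD noise statistics, specular BRDF effects, juice chemistry differences
(potato vs spinach), wavelength miscalibration, or non-circular residue
shapes. They do show that every algorithmic stage is internally correct
and recovers designed ground truth under controlled difficulty.

## Droplet masking

* **Otsu route.** The 720 nm feature band (strongest absorption) is
  enhanced (3 × 3 median filter, then unsharp mask with radius 1 and
  amount 1), percentile-stretched (2nd/98th) to 8 bits, and thresholded by
  Otsu's between-class variance maximizer (own implementation, exhaustive
  over the 256-bin histogram; deterministic, lowest level on ties). The
  darker-and-smaller side becomes the droplet mask — droplets are always
  the minority phase on a plate. Fixed 8-bit presets (110 for spinach, 98
  for potato) are shipped as named constants for parity with published
  practice, but recomputation per image is the default. The enhancement
  step is meant for noisy images; on noise-free plates the unenhanced
  route reproduces the truth mask pixel-for-pixel, while unsharp ringing
  costs a thin boundary band (IoU ≈ 0.96).
* **PCA route.** The pixels × bands matrix is mean-centered and projected
  on PC1; the score image is Otsu-thresholded with the same
  minority-phase polarity rule.
* **Labeling.** Masks are cleaned by an area filter (default: 25% of the
  layout droplet area) and labeled as 8-connected components, numbered in
  raster order of their first pixel, so ids are independent of the mask's
  provenance. Droplets are assigned dilution classes by nearest layout
  grid position; centroids farther than half a grid spacing are flagged
  unassigned with a warning.
* **Background sampling.** Twelve non-overlapping square regions (10 px,
  seeded rejection sampling) are drawn disjoint from the dilated droplet
  mask; they provide the *BG* training spectra.

## U-net segmenter

Encoder–decoder with skip concatenations, implemented on the package's
numpy NN core (no framework dependency):

* four encoder blocks of two same-padded 3 × 3 convolutions + ReLU with
  2 × 2 max pooling; channel ladder 32 → 64 → 128 → 128 (the doubling
  ladder capped at 128, so the deepest skip concatenates two 128-channel
  maps into a 256-channel map);
* a 128-channel bridge; dropout 0.5 at the deepest encoder level and the
  bridge (training only);
* decoder of 2 × 2 stride-2 transposed convolutions, skip concatenation
  and two 3 × 3 convolutions per level; final 1 × 1 convolution to one
  sigmoid channel.

Inputs must be divisible by 2⁴ = 16 per axis (the pipeline pads
reflectively and crops back). Training minimizes pixel-wise binary
cross-entropy with Adam (lr 10⁻³, batch 2); weight init, dropout and batch
shuffling all derive from one seed, so fits are bit-reproducible.

Training data are randomized 128 × 128 synthetic pairs whose per-droplet
effective optical depth is drawn log-uniformly on [0.03, 2.5] (≈3%–92%
contrast), with ±3 px center jitter and ±1 px radius jitter. Spanning the
faint end is essential: a network trained only on strong droplets does not
generalize down to near-noise contrast. "Low-contrast plates" in the
evaluation are mixed plates with depths on [0.02, 1.0]; there a global
threshold anchors on the stronger droplets and sheds roughly half of all
droplet pixels, while the U-net's spatial context keeps recall near 1 at
precision near 1 — the qualitative advantage claimed for learned masking.

## Spectral pretreatments

Savitzky–Golay derivatives use window 11, polyorder 2 (common VNIR
practice; the derivative is taken with respect to band index). The moving
average uses window 5. Both use mirror padding so all methods are
length-preserving (128 → 128). MSC regresses each spectrum on the
training-set mean (`x = a + b·ref`) and returns `(x − a)/b`; the reference
learned at fit time is reused at transform time. "Normalization" is
per-spectrum min–max to [0, 1]; SNV is available behind the same
transformer for users who read normalization as standardization. All
methods preserve sample count and labels; constant spectra and degenerate
MSC slopes (|b| < 10⁻⁸) raise rather than emit NaNs. Pretreatments are
applied one at a time (no chaining), mirroring how such method comparisons
are tabulated.

## Chemometric classifiers

LDA, PLS-DA and LSSVM are implemented from their defining linear algebra;
SVM, decision tree and random forest delegate to scikit-learn behind the
same scikit-learn-compatible estimator surface. Defaults and numerical
choices:

* **LDA** — pooled within-class covariance with Ledoit–Wolf shrinkage
  toward `tr(S)/d · I` (estimated on the within-class residuals). With
  hundreds of correlated bands and sample counts near the dimensionality,
  the unshrunk pooled covariance is invertible but noise-dominated;
  shrinkage is the standard remedy and costs nothing in well-conditioned
  regimes. A singular matrix additionally falls back to a small ridge
  with a warning.
* **PLS-DA** — NIPALS PLS2 on centered one-hot targets, 10 components by
  default (capped at the rank of X), decision by argmax of the predicted
  responses. At full rank it reproduces ordinary least-squares one-hot
  regression exactly, which is the oracle used to test it.
* **SVM** — RBF kernel, `γ = 'scale'` (variance-adaptive), `C = 10`.
  On raw reflectance, fixed per-dimension γ leaves adjacent-dilution
  kernel contrasts orders of magnitude below the regularization scale (the
  Gram matrix degenerates toward all-ones), stalling the fit at chance
  even on noise-free data; the variance-adaptive length scale plus a
  moderately large C is robust across both raw-reflectance and
  standardized-scale inputs.
* **LSSVM** — one-vs-rest; the dual linear system
  `[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` is solved directly
  (γ = 10, RBF width defaulting to the median pairwise training distance);
  a singular system gets a 10⁻¹⁰ ridge bump with a warning. Asymmetric
  kernels are rejected.
* **DT / RF** — scikit-learn with seeded determinism; RF defaults to 500
  trees, majority vote with ties broken toward the lowest class index in
  the fixed order (*Hundred*, *Twenty*, *Ten*, *Five*, *Two*, *One*, *BG*),
  which is the class order used everywhere (confusion matrices, reports).

Cross-validation is leave-one-out: n independent fits, each omitting one
sample, aggregated into a single 7 × 7 confusion matrix. Folds missing a
class still run, with a warning.

## 1-D CNN

Fixed architecture for 128-band input and 7 classes (valid convolutions,
stride 1, ReLU):
conv(40 filters, k=5) → average-pool(2) → max-pool(2) →
conv(20 filters, k=3) → average-pool(2) → max-pool(2) → flatten(140) →
dense(500) → dropout(0.5) → dense(100) → dense(7, softmax). The kernel
sizes 5 and 3 are the unique choices consistent with the published output
lengths (128 → 124, 31 → 29) and parameter counts (240 and 2,420); the
dropout rate mirrors the U-net's 0.5. Total trainable parameters: 123,967.
Training minimizes categorical cross-entropy with Adam (lr 10⁻³, batch 32);
per-epoch loss and the mean absolute error of the class probabilities are
recorded. The default schedule is 500 epochs with optional plateau early
stopping (the published account gives both 500 and 5000; 500 is the
default, 5000 reachable by config). Data are split 70/30 stratified into
calibration and validation subsets, and accuracy is reported separately
(`Ac`, `Av`). Whether samples are pixels or per-droplet means is the
caller's choice; the pipeline uses per-pixel spectra.

## Evaluation

Confusion matrices use rows = true, columns = predicted, in the fixed
class order. `A = trace/total`; per-class accuracy is class recall
(diagonal over row total; precision is the other defensible reading — the
choice matters when comparing against external tables), with NaN marking
classes absent from the truth. Cohen's kappa uses
`p_e = Σ row_i·col_i / n²`; a one-class matrix (`p_e = 1`) raises rather
than returning a meaningless value. Reports are long-format CSV
(method × preprocessing × per-class × A × K) at full precision, displayed
at two decimals.

## Problem sizes and determinism

Test and demonstration runs use the scaled-down defaults chosen above:
256 × 220 plates, 128 × 128 segmentation crops, 20 training pairs /
30 epochs for the U-net, 700 spectra / 200 epochs for the CNN recovery
check, and ≤ 30 spectra per class in LOO pipelines. These sizes make the
entire suite reproducible on a single CPU while leaving every contract
(shapes, counts, invariants) identical to full-scale runs. All randomness
flows from explicit seeds; the pipeline derives per-stage seeds from the
master seed via CRC-hashed seed sequences, so stage re-runs match full
runs and identical configs reproduce reports byte for byte.

## Known limitations

* The simulator's noise is i.i.d. Gaussian on counts; real EMCCD noise is
  signal-dependent, and line-scan systems stripe.
* Per-pixel classification ignores spatial correlation within droplets; a
  per-droplet aggregation (mean spectrum per labeled droplet) is available
  but not the default.
* The U-net is trained on synthetic band images only; applying it to real
  plates would require annotated real masks or domain adaptation.
* PLS-DA with few components underperforms on raw reflectance of
  fine-grained dilution series; derivatives or MSC pretreatments are
  advisable for it.
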