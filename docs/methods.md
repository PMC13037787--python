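# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments can show. It states nothing that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Region-wise gradient scoring

The quantity of interest is the sensitivity of one predicted region to the
trained weights. For a region *R* (a connected component of the predicted
label map) with *N* voxels and per-voxel predicted-class softmax
probabilities `p_i`, the regional target is either

* `kl`: `T_R = (1/N) Σ p_i ln(p_i / (1/C))`, the KL divergence to the
  uniform reference `q = 1/C` (natural logarithm; `p_i` clamped to
  `[1e-12, 1]` before the log), or
* `mp`: `T_R = (1/N) Σ p_i`, the mean probability.

`T_R` is backpropagated alone — the gradient seed is zero everywhere except
the region's predicted-class channel — and the Local Gradients score is the
L1 norm of the gradients over the selected decoder blocks. Per-region
backward passes share one forward pass per image (activations are cached and
keyed on the input's object identity) and gradient buffers are zeroed
between regions, so a region's score is independent of whatever else is in
the image; the test-suite asserts this isolation to 1e-10 and asserts that
weights are bit-identical after scoring.

Choice of logarithm base only rescales all scores jointly and cancels in the
P95 normalization. The `p_i` entering the targets is the scalar probability
of the region's own (argmax) class — multi-class models feed the
predicted-class channel, not a full per-voxel distribution.

Gradients are taken with respect to *all* learnable parameters of the named
blocks: convolution weights and biases and the normalization affine
parameters. The L1 norm is additive over disjoint parameter sets, which the
block-sensitivity sweep exploits: one backward pass per region and target
yields every block configuration's score.

## The toy segmentation model

No deep-learning framework is assumed; the bundled model is a small 2-D
encoder–decoder with equal-resolution skip connections written in NumPy
(float64) with hand-written backpropagation. Decoder convolutional blocks
are named `Block_<level>-<pair>` with level 0 at the bottleneck and two
blocks per level; `levels = L` exposes `2L` decoder blocks, and the default
gradient target is the two blocks of the highest-resolution level (on a
five-level decoder: `Block_4-0`, `Block_4-1`).

Each block is conv3×3 → instance normalization (affine) → GELU. GELU is
used rather than ReLU deliberately: the activation is smooth, so the
gradient is defined everywhere and backprop can be held to a strict central
finite-difference comparison (relative 1e-3 over ≥ 20 random draws on a
sub-5k-parameter instance) without kink artifacts. Down/upsampling are 2×2
average pooling and nearest-neighbor repetition (both linear). The softmax
head gives per-voxel class probabilities.

Training minimizes cross-entropy plus soft Dice over foreground classes
(smoothing constant 1.0) with Adam (lr 3e-3, β = 0.9/0.999), batch size 8.
Everything — initialization, shuffling, noise — is driven by explicit seeds,
so training is bit-reproducible.

Whole-image forward passes are used throughout; sliding-window patch
inference of production pipelines is out of scope at this image size. The
scoring machinery itself is model-agnostic: anything implementing the
`DifferentiableModel` contract can be scored.

## Calibration

`U_LG = LG / P95{LG_low}`, where the constant is the 95th percentile
(linear interpolation between order statistics) of scores from regions
assumed low-uncertainty. Two reference-set styles are supported through the
same call: confident validation predictions, or true-positive regions.
Constants are per trained model and per measure. The probability-derived
baselines grow with confidence, so they are negated after scaling:
`U_MP = −MP / P95`, `U_KLD = −KLD / P95`; all three measures then increase
with uncertainty. A non-positive percentile (e.g. all-zero scores) is a
degenerate calibration and raises rather than silently flipping signs.

## Regions and detection labels

Connected components use face connectivity (6-neighborhood in 3-D,
4-neighborhood in 2-D) by default, configurable to full connectivity.
Volumes are physical (`voxels × ∏spacing / 1000`, cm³), so the standard
small-object filter (0.25 cm³ in clinical pipelines) is resolution
independent; the phantom experiments use 0.1 cm³ (16 voxels at 2.5 mm
spacing) because the 2-D phantom lesions are themselves small. A predicted
region is a false positive iff it shares zero voxels with any nonzero truth
voxel — one shared voxel makes it a true positive; no minimum overlap
fraction is imposed. Region ids are ordered by each component's first voxel
in row-major order, which makes every downstream artifact deterministic.

Region matching across degraded images is greedy full-overlap enumeration:
a baseline region links to every region it shares a voxel with, so splits
and merges both appear. When a tracked region splits, the split parts'
uncertainty values are volume-weighted. A region present at every
degradation magnitude is *persisting*; percent-difference analyses are
restricted to persisting regions. Longitudinal tracking with growth models
is out of scope.

## Degradations

Additive Gaussian noise `I + W`, speckle `I(1 + W)`, Gaussian smoothing
(reflective boundaries, kernel truncated at 4σ). Sweeps run 11 evenly spaced
magnitudes from zero; the zero magnitude returns the input bit-exactly, and
each magnitude draws an independent noise field seeded from the sweep seed
and step index. The noise σ acts on intensity units, only the smoothing σ is
spatial. Default grid endpoints (70 / 1 / 4) suit CT-scale intensities; the
phantom experiments use σ_max = 0.45 for additive noise (three times the
phantom background noise, lesion amplitudes near 1) so the sweep spans
"barely perturbed" to "heavily corrupted" at unit intensity scale.

## Evaluation metrics

* ROC AUC in the Mann–Whitney form (ties credited 0.5), with FP regions as
  the positive class flagged by high uncertainty.
* FPR95: of the thresholds (score ≥ t) capturing at least 95% of FP regions,
  the one with the lowest TP-flagging rate; that rate is returned.
* Percent differences: per-track `100 (U_σ − U_0)/U_0` (undefined for zero
  baselines, which raise), summarized as medians with IQR across persisting
  tracks; between groups, `100 (med A − med B)/med B` — the group-median
  form, since compared groups are unpaired.
* Rank tests are thin contracts over scipy.stats (two-sided signed-rank /
  rank-sum); all-tied paired differences return the sentinel p = 1. Both
  metrics are pinned to brute-force oracles (pair enumeration, threshold
  scan, exact permutation enumeration) in the tests.

## What the phantoms emulate — and what they do not

Phantoms are 2-D 48×48 images (the method is dimension-agnostic; regions,
degradations and calibration are N-D, and 2-D keeps the full pipeline under
minutes): 1–3 Gaussian-profile lesions (half-maximum radius 3–5.5 voxels,
amplitude 0.9–1.5) on iid Gaussian background noise (σ 0.15), truth labels
at the blobs' half-maximum footprint. 60% of images carry a *distractor*
blob with amplitude 0.6–1.1 that is background in the truth. The overlap of
the two amplitude bands is the point: blobs near the decision boundary are
genuinely ambiguous, so a trained model produces honest false positives at
reduced confidence — the mechanism behind benign mimics in clinical lesion
detection — rather than label-corruption artifacts. Multi-class phantoms
give each class a distinct amplitude band (scale `1 + 0.7(c−1)`).

Computed on the standard conditions (200 training phantoms, 10 epochs, 100
validation phantoms), the pipeline reaches held-out foreground Dice ≈ 0.8,
false positives separate from true positives with AUC ≈ 0.7–0.8 and rank-sum
p < 0.01, and median U_LG over persisting regions rises monotonically
(Spearman ρ ≈ 0.98) across the additive-noise and speckle sweeps — see
`scripts/acceptance.py` for the exact numbers per seed.

Known limitations of the stand-in:

* Smoothing acts as *denoising* here: the phantom's only texture is iid
  noise, so Gaussian smoothing cleans the image, predictions become more
  confident, and U_LG *falls* with smoothing magnitude — the opposite of
  what degraded clinical texture produces. The smoothing sweep is therefore
  reported but not used as a direction check.
* Phantom intensities are unit-scale and single-channel; no modality physics
  (CT sinogram noise, PET reconstruction) is modeled.
* The toy model is orders of magnitude smaller than clinical networks;
  absolute score magnitudes and clinical effect sizes do not transfer. What
  the passing tests establish is the method's *mechanics* (exact gradients,
  isolation, calibration algebra, metric definitions) and its qualitative
  behavior (FP separation, noise response) under controlled conditions.

## Numerical conventions

* float64 throughout; probability floor 1e-12 in the log targets, 1e-8 in
  the training loss; instance-norm ε 1e-5.
* Percentiles: linear interpolation between order statistics.
* Ties: AUC credits 0.5; majority-class votes break toward the smallest
  class index; region ids break ties by row-major first voxel.
* Empty inputs raise typed errors (`EmptyRegionError`,
  `DegenerateCalibrationError`, `GridMismatchError`, ...) rather than
  returning sentinels, except where a sentinel is the documented contract
  (unmatched majority class → `None`; all-tied paired rank test → p = 1).
* 0-based voxel coordinates and half-open bounding boxes in every
  serialization.
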