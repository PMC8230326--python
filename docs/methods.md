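# Methods

## Scope and model

`nucseg` studies how image bit depth and intensity preprocessing affect
nuclei instance segmentation in single-channel fluorescence images. The
pipeline has five computational stages — synthetic scene generation,
preprocessing/requantization, training-target construction, two-stage
watershed-merged segmentation, and evaluation/statistics — each usable on
its own.

## Synthetic scenes

The generator emulates the statistical structure of a fluorescence
nuclei crop collection: 16-bit single-channel fields (512×512 by
default), a magnification-dependent expected nuclei count, touching
nuclei, and rare saturated hot-spot artefacts. Four presets carry the
per-objective mean counts 145.5 (20× air), 47.2 (40× air), 38.1 (40×
oil) and 19.4 (63× oil) nuclei per field, with semi-axis ranges scaled
to the objective (4–8 px at 20× up to 12–20 px at 63×).

Per scene, the nucleus count is Poisson(mean_count) — the standard point
process default. Nuclei are mildly eccentric rotated ellipses
(minor/major axis ratio in [0.75, 1]); a `touch_fraction` (default 0.25)
of them is placed against a neighbour at 85–95% of the sum of effective
radii, guaranteeing instances that only the distance stage can separate,
while the rest are rejection-sampled to stay separated. At shared pixels
the later nucleus wins the label, so labels always partition the
foreground (required for AJI/PQ to be well defined).

Intensity model: per-nucleus peak drawn uniformly from 35–80% of full
range (inter-nucleus contrast variation), radial profile
`0.15 + 0.85·(1 − r²)^0.25` — a bright plateau with a steep shoulder, as
chromatin-filled nuclei image under a PSF-limited microscope — plus
Gaussian pixel noise (σ = 0.5% of full range). The dome-shaped
alternative (`sqrt(1 − r²)`) was rejected: it puts a wide dim shoulder
inside the ground-truth boundary that no global threshold recovers, so
the labelled boundary would be unrecoverable by construction. Background
is a dark Gaussian floor (mean 2%, σ 0.6% of full range, clipped at 0);
hot-spots are Poisson-many (default rate 2) few-pixel spots at exactly
65535, placed on background only, which is what makes 99th-percentile
outlier clipping observable. `easy_preset` switches a preset to its
high-contrast variant (no touching nuclei, no hot-spots) for
parameter-recovery experiments.

The generator does **not** model chromatin texture, PSF blur of edges,
vignetting/illumination gradients, camera shot noise statistics, or 3-D
effects. Tests passing on these scenes therefore demonstrate the
pipeline's internal correctness and the bit-depth mechanics, not
performance on real acquisitions.

## Preprocessing

The four variants (D1 divide-by-full-range; D2 = D1 + 99th-percentile
clip, rescaled; D3 min/max; D4 clip-then-min/max) follow the orderings
exactly as named: D2 clips the already-normalized image, D4 clips raw.
Percentiles use the lower nearest-rank estimator (the ⌈p·n/100⌉-th
smallest pixel): exact, deterministic and portable; the clip threshold is
always an actual pixel value, so integer images stay integer. Min/max
normalization on a constant image raises a typed `DegenerateImageError`
rather than emitting NaNs.

Bit-depth reduction uses `round(x / 2^(16−b))` with round-half-away-from-
zero and clamping into `[0, 2^b − 1]` — clamping is forced because
round(65535/256) = 256 would overflow 8 bits. b = 16 is the identity. The
b-bit study input is defined as requantization followed by D4, so all
depths enter the segmenter in [0, 1]. Resolution harmonisation resizes
images bilinearly and label masks by nearest neighbour (labels must not
be interpolated).

## Training targets

From a label mask the pipeline derives: the binary mask; the per-object
Euclidean distance transform max-normalized per object (scale-free
regression targets peaking at 1 regardless of nucleus size); the
touching-border weight map `1 + w0·exp(−(d1+d2)²/(2σ²))` with defaults
w0 = 10, σ = 5 px (the canonical border-emphasis weighting; with fewer
than two instances it is uniformly 1); and the border-removed mask
(per-instance disk erosion, default width 1 px, minimal so small nuclei
survive). ImageJ ROI outlines (polygon, freehand, traced, rectangle,
oval) are rasterised with interior and boundary included, later polygons
overwriting earlier ones.

## Segmentation and merging

Two backends satisfy one predictor contract (map in [0, 1], same shape
as input; raw integer input is refused with a typed error, since
training on unnormalized intensities does not converge):

* **classical** — foreground by Otsu threshold; distance by
  per-connected-component max-normalized exact EDT of that thresholded
  map. Deterministic and training-free; the default for study runs and
  the acceptance surface.
* **trained** — a seeded SGD pixel model over multiscale features
  (Gaussian blurs at σ = 0, 1, 2, 4, 8, Laplacians at σ = 2, 4, bias),
  standardized on the training set; logistic output with binary
  cross-entropy (optionally weighted by the border weight map) for the
  foreground stage, linear output with MSE for the distance stage.
  Optimisation follows the study schedule: initial learning rate 0.01
  halved after every 8 epochs, batches of 4 images, 30 epochs by
  default; flips, 90° rotations and ±10% brightness / 0.9–1.1× contrast
  jitter are applied to training images only; per-epoch loss is recorded
  on the clean images. This is a deliberately small model chosen for
  CPU-scale experiments, not an encoder–decoder network.

The merge thresholds the foreground map (default 0.5), takes h-maxima of
the distance map (default depth 0.1) inside the foreground as seeds, and
floods the negated distance map with a marker-controlled watershed;
components under `min_object_area` (default 10 px) are dropped and labels
made consecutive.

Two numerical details matter here. Seeds are labelled with
8-connectivity, so a diagonal plateau of maxima is one seed. And the
seed-detection basis is the distance map smoothed with a small Gaussian
(`seed_smoothing_sigma`, default 1 px): a discrete EDT routinely has two
pixels tied at exactly the per-object maximum, and tied equal-height
peaks survive *any* h-maxima depth (the reconstruction residue equals h
at the twin peak), which would split single nuclei. Smoothing only the
seed basis resolves the ties; the watershed itself still floods the raw
negated distance map. Watershed flooding order makes plateau tie-breaks
deterministic.

## Evaluation

Dice, AJI and PQ are computed from a sparse pairwise overlap table. AJI
follows the original aggregated-Jaccard formulation: each ground-truth
instance is matched to the prediction maximising the Jaccard index (ties
to the lowest prediction label); a prediction may be the argmax of
several ground-truth instances and is then counted in each pair; unused
predictions are added to the denominator. PQ matches at IoU strictly
above 0.5, which makes matches provably unique. Degenerate conventions:
empty ground truth with a non-empty prediction scores 0 on all three
indices; two empty masks score 1; both cases set a flag so study
summaries can report such images separately. All scores are invariant
under label permutations and joint spatial transposition; these
invariants, plus agreement with an independent brute-force evaluator,
are enforced by tests.

## Study harness

Cross-validation uses a seeded shuffle with round-robin assignment
(fold sizes differ by ≤ 1; folds are unstratified, matching a simple
fixed-seed design). An experiment is (bit depth, variant, backend,
merge parameters); records are returned in dataset order, so two
experiments on the same scenes and folds are paired image-by-image —
comparisons never mix images, folds or seeds. The Wilcoxon signed-rank
test is two-sided with zero differences discarded, exact null for small
n and a continuity-corrected normal approximation otherwise (scipy's
`wilcoxon`); all-zero differences report p = 1 with a warning. The
Bonferroni divisor is 3 (the three metrics), giving the 0.017 level;
because the three metrics are correlated this correction is
conservative, which the comparison output leaves to the reader rather
than adjusting. The bit-depth sweep runs one experiment per depth with
D4 preprocessing and emits mean ± SD per metric; the
difference-versus-count analysis pairs per-image |ΔAJI| / |ΔPQ| with
ground-truth nuclei counts and attaches a descriptive Spearman rank
correlation.

## Problem sizes and defaults in the test/acceptance suite

The shipped experiments are sized for a single CPU: parameter recovery
uses 20 easy 512×512 63×-like scenes; the bit-depth trend uses 16
default 63× scenes at 256×256 with five folds; null calibration uses 500
replicate simulated studies of 20 paired images; the trainable-backend
check trains 5 epochs on 20 scenes of 128×128 and evaluates 4 held-out
scenes. All randomness flows from explicit integer seeds; identical
seeds reproduce results bitwise.

## Known limitations

* The classical backend's global Otsu threshold under-performs when
  nucleus brightness spans a wide range in one field; it is a
  deterministic stand-in, not a learned model.
* The trainable backend is a pixel-feature model without spatial
  decoding; it cannot learn shape priors.
* AJI's known pathology (one prediction counted in several pairs) is
  reproduced faithfully because the study depends on the published
  definition.
* The synthetic hot-spot model is a plausible stand-in for acquisition
  artefacts, not a fit to any real camera.
* 3-D stacks, multi-channel immunofluorescence and photorealistic
  texture are out of scope.
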