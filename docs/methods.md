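# Methods

## Problem setting

During clinical dictation a radiologist's gaze and speech are coupled:
the reader looks at a finding shortly *before* and while speaking the
sentence that reports it, and scans the whole image during silent
intervals. `gazemil` exploits this coupling twice:

1. **Extraction** — converting a reading session (gaze fixations plus a
   word-timestamped transcript) into one localization heatmap per
   reported abnormality label, with no manual annotation; and
2. **Supervision** — training a grid-based multilabel classifier whose
   per-cell predictions are supervised by those heatmaps through a
   multiple-instance-learning (MIL) loss, alongside an auxiliary
   decoder that reconstructs the heatmaps at high resolution.

## Mention detection

Transcripts are segmented into sentences at sentence-final punctuation.
A phrase matcher with a shipped, versioned vocabulary maps source terms
onto the ten study labels (Abnormal Mediastinal Contour, Atelectasis,
Enlarged Cardiac Silhouette, Consolidation, Edema, Fracture, Lung
Lesion, Opacity, Pleural Abnormality, Pneumothorax). The grouping is
many-to-many: "pulmonary edema" asserts both Edema and the umbrella
Opacity label. Matching is longest-phrase-first per label; `unmatch`
phrases block matches they contain ("mass effect" vs "mass"). A mention
is negated when a cue ("no", "without", "negative for", ...) precedes
it within the sentence. Hedged statements ("possibly", "may
represent") count as positive by default, with a configurable option to
drop them; the labeler is deliberately a transparent, editable stand-in
for a full report-labeling rule engine — labeler noise degrades
downstream localization gracefully rather than invalidating the
pipeline.

## Window rule and heatmap rendering

For each non-negated mention, fixations are taken from the window

```
t0 = max(previous sentence start, mention sentence start − delay)
t1 = end of the last mention in the sentence
```

with `delay = 1.5 s` by default — i.e. the shorter of "since the
previous sentence began" and "1.5 s before the mentioning sentence".
For the first sentence the recording start substitutes the previous
sentence. Fixations partially overlapping the window are included with
their overlap as duration (the rule is insensitive to window-edge
effects). Each selected fixation contributes a Gaussian at its
location, amplitude-weighted by duration, with standard deviation one
degree of visual angle (per-fixation calibration metadata when present,
else a configurable constant of 85 px/deg at the 512-px working
resolution); Gaussians are truncated at 4 sigma (tail < 3.4e-4 of
peak). Each mention's map is normalized to maximum 1, and multiple
mentions of a label are combined by pixelwise maximum, so aggregation
is associative, commutative and idempotent, and every mentioned site
peaks at 1.

The window policy is explicit configuration: eight start rules, four
end rules and a delay grid can be swept against gold masks
(`sweep_policies`), selecting the binarization threshold that maximizes
mean IoU per policy. The two-stage delay grids (stage 1: 2.5/5/7.5 s;
stage 2: 0.5–5 s in steps down to 0.25 s) are built in.

## Grid conversion

Images are letterboxed (longest side to 512 px — or the configured
working size — short side zero-padded). Heatmaps take the same
transform, are thresholded at 0.15 and max-pooled to the encoder grid
(32x32 at 512 px, i.e. input/16) and to the decoder target resolution
(input/2). Since `max` and `> t` commute, threshold-then-pool equals
pool-then-threshold exactly; the package implements threshold-then-pool
and asserts the equivalence, which also makes the letterbox-vs-
threshold order immaterial. Ellipse masks pass through the identical
path. Padding cells are always negative.

## MIL loss with balanced range normalization

With per-cell logits γ_jk over grid cells Γ and σ the sigmoid, the
image-level probability is the soft OR

    C_k(x) = 1 − Π_j (1 − σ(γ_jk)).

Losses per (image, class): annotated images use a per-cell
cross-entropy against the annotated cell set B_kx written as one
log-product; unannotated positives use −log C_k; unannotated negatives
use −log Π_j (1 − σ(γ_jk)). These combine as

    L_I = E[ λ_A·1_A·L_A + 1_U+·L_U+ + 1_U−·L_U− ],   λ_A = 3.

Products of ~1000 factors in (0,1) underflow, and their scale depends
on the factor count, so every factor is affinely remapped onto
[0.0056738^(1/nt), 1] with nt the factor count ("balanced range
normalization"): the product of floor-valued factors is 0.0056738 for
any grid size, and the per-factor range reproduces the earlier fixed
[0.98, 1] scheme exactly at nt = 256. `fixed_098` and `none` modes are
available for ablation. `nt` for the annotated loss is the full cell
count |Γ| (the loss is one product split over B and its complement).

All products are computed in log space. The unannotated-positive loss
−log C_k needs care when every complement factor rounds to exactly 1
(all σ underflow): it is then evaluated through its asymptotic form
−logsumexp(log(1−lo) + log σ(γ_j)), keeping values and gradients finite
for logits of any magnitude — the numerical guarantee the normalization
exists to provide. Equivalence with extended-precision (80-bit) direct
products is asserted to 1e-10 on small grids.

## Multi-task decoder loss

The decoder produces one logit map per label at half working
resolution; its loss is pixel-level binary cross-entropy against the
binarized gaze map, applied only to channels whose label is
annotated-positive (other channels contribute zero), averaged over the
batch x class expectation. The total objective is L = L_I + λ_T·L_T
with λ_T = 300. Whether the inner term averages or sums over pixels is
a free convention absorbed by λ_T; the mean is used.

## Architecture

The encoder's classification head replaces global pooling + linear
layer with two convolutions separated by batch normalization and ReLU,
keeping predictions spatial (one logit per cell per class). With
multi-resolution fusion, the output of every trunk stage is resampled
bilinearly to grid resolution and concatenated before the head, so
fine-resolution evidence for small findings reaches the classifier
directly. Branch features are concatenated (not summed) — the fusion
choice is a reconstruction, faithful in structure but not bit-level
prescribed. Two trunks exist: `tiny` (four strided conv blocks,
~135k parameters — the desk-scale default) and `resnet50_shaped`
(bottleneck stages 3-4-6-3), selected by config. The decoder is three
blocks of (bilinear x2 upsample, 3x3 convolution, batch norm), grid
resolution to input/2, ten output channels.

Because no tensor framework is assumed, the package carries its own
small reverse-mode autodiff engine (`gazemil.autodiff`, `gazemil.nn`):
tape-recorded numpy primitives, fused conv/batch-norm/resize ops with
analytic backwards, and an AMSGrad optimizer. Gradient correctness is
established against central finite differences in the test suite.

## Training protocol

Full-scale defaults mirror the reference protocol: 60 epochs, AMSGrad
(lr 0.001, weight decay 1e-5), batch 20, augmentation with rotation up
to 45 degrees, translation up to 15% and scaling up to 15% (identical
transform for image and annotation maps, re-binarized after
interpolation), five seeds, best epoch per method by mean validation
AUC. The binarization threshold per method and label is chosen by mean
validation IoU across seeds over a full threshold grid (ties to the
lower threshold); the heatmap source per method (decoder output vs
spatial activations) by validation IoU, ties to the simpler spatial
source. Test IoU is computed per positive (image, label) pair after
nearest-neighbor upscaling to mask resolution, then averaged per label
and across labels; AUC per label from the soft-OR probabilities, with
single-class labels reported as absent.

The *Unannotated* baseline marks every image unannotated (indicator
routing, no separate code path); *Ellipse* feeds ground-truth masks
through the identical annotation path as the gaze heatmaps.

## Synthetic cohorts

The generator emulates exactly the behavioural structure the extraction
assumes, with all latent variables known:

- **Images** (default 128 px for desk scale): smooth Gaussian-filtered
  background texture plus additive elliptical intensity bumps (semi-axes
  8–18% of image size, contrast 0.3–0.5) at label-characteristic
  anchor locations (loosely anatomical; what matters is that labels are
  spatially distinguishable, as anatomy makes them in practice), pixel
  noise sigma 0.03.
- **Transcripts**: an initial 4 s silent interval, one short sentence
  per dictated positive finding using the labeler's own vocabulary
  phrases (closing the loop end to end), ~2.5 words/s with ~2 s pauses,
  and negated distractor sentences about absent findings at rate 0.3.
  The Opacity grouping is honoured: member findings imply Opacity with
  the member lesion inside its mask.
- **Gaze**: ~3 fixations/s with log-normal durations; uniform scanning
  outside mention periods; during a window from `gaze_lag` (default
  1.5 s) before each mentioning sentence until its mention ends,
  fixations are drawn around the dictated lesion's centre (dispersion
  6% of image size), with a 15% stray-fixation fraction. Angular
  calibration is written per fixation as 5% of image width per degree —
  a radiograph on a reading workstation subtends roughly 20 degrees of
  visual field.

What the generator does *not* model: realistic radiograph appearance,
saccade dynamics and reading-order habits, within-sentence gaze drift,
correlated label co-occurrence beyond the Opacity grouping, and
annotator disagreement. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is
present — parameter recovery, ordering of supervision regimes,
correctness of the losses — not clinical-grade performance on real
reading sessions.

## Desk-scale experiment sizes

The package's own experiments (tests and `scripts/acceptance.py`) run a
reduced configuration chosen to keep a full run on one CPU core
comfortable: 128-px images, tiny backbone, 60 annotated + 120
unannotated training cases, 40 validation / 60 test cases, 10 epochs,
batch 20, 3 seeds; the window-policy sweep uses 50-case cohorts over 5
generator seeds. With these sizes the three-way supervision comparison
reproduces the qualitative result of the full-scale study: localization
IoU orders Unannotated < gaze-supervised <= Ellipse-supervised while
mean AUC differs by well under 0.05, and model selection independently
picks the spatial activations for the Unannotated model and the decoder
output for the supervised ones.

## Numerical and design choices

- Time is float seconds everywhere; readers convert declared-unit
  milliseconds.
- Empty windows (t1 < t0) yield empty fixation sets, not errors; a
  policy whose windows are all empty is excluded from sweep tables.
- Heatmaps with zero fixations are all-zero (no division by zero); an
  off-image fixation can render an empty map, which stays legal.
- Threshold ties and heatmap-source ties break toward the lower
  threshold and the simpler source, deterministically.
- The final decoder block keeps its batch normalization on the logit
  maps (affine, learnable), matching the stated block structure.
- Checkpoints embed the architecture config and reload bit-identically.
- Confidence intervals over seeds, where reported, are t-intervals.

## Known limitations

- The labeler is a phrase matcher, not a clinical NLP system; its
  vocabulary is configuration, with no claim of equivalence to any
  production labeler.
- The numpy backend is single-threaded-BLAS fast, adequate for
  desk-scale cohorts; the `resnet50_shaped` trunk at 512 px is
  supported for completeness but impractical to train in this backend.
- IoU at extraction time depends on the angular-calibration constant;
  with uncalibrated data the 85 px/deg default must be reviewed.
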