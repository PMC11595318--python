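# Methods

## The discrepancy statistic and decision rule

Binocular movements are yoked: in an aligned subject both eyes share one
gaze offset, so the contralateral eye's image predicts a pupil position.
The screener exploits this with two estimators of the same pupil —
direct (own crop → own pupil) and cross-eye (opposite crop → this pupil,
in this crop's normalized frame) — and measures their Euclidean distance D
per eye, in model-input pixel units (normalized estimates × input size).

Both per-eye distances respond to a unilateral deviation.  If the right
eye deviates by δ, the cross estimate of the right pupil (computed from
the *left* crop, which is unaffected) disagrees with the right eye's
direct estimate by ≈ δ; symmetrically, the cross estimate of the *left*
pupil is computed from the deviated right crop and is wrong by ≈ δ as
well.  The per-eye statistic therefore localizes the misalignment event,
not reliably the deviated eye.

Thresholds are Θ = µ + K·σ per eye, fitted on non-strabismic calibration
units (µ arithmetic mean, σ sample SD with n−1; K = L = 1.5 default;
thresholds carried at full precision and rounded only for display — the
published worked example only reproduces at full precision: 5.3017 +
1.5 × 0.6038 = 6.2075 → 6.21, whereas 2-dp inputs would give 6.20).
Although the threshold definition can be written with ±, only the upper
bound is a decision boundary.  A unit is strabismic iff either eye's
distance strictly exceeds its threshold; ties classify as normal because
the normal rule is "less than".  Calibration units and screening units
must match: per-video means for video screening (`unit_kind="video_mean"`),
per-image distances for still screening.  Distances are tied to the model
input size, so calibration and screening must share it (enforced).

### Operating characteristic of µ + 1.5σ

The K = 1.5 rule fixes the normal-side exceedance: if calibration and test
units are exchangeable and roughly Gaussian, each eye exceeds its
threshold on ≈ 6.7% of normal units (plus threshold-estimation noise from
a finite calibration sample).  Under the either-eye OR rule the unit-level
false-positive rate is ≈ 7–13% depending on how strongly the two eyes'
distances co-vary (shared subject difficulty correlates them and pushes
the rate toward the single-eye tail).  Specificity measured on a batch of
normal clips therefore fluctuates around ≈ 0.9; a 20-clip batch commonly
lands anywhere in 0.8–1.0.  Sensitivity at deviations several times the
normal residual scale is far less delicate — deviated clip means sit an
order of magnitude above the thresholds.  Raising K trades false
positives for sensitivity to small deviations.

### Mean-based video classification

Per-video classification compares the *mean* retained-frame distance to
Θ, matching how the thresholds are calibrated.  A deviation active in only
a minority of frames dilutes into the mean and can be missed (the worked
example's intermittent clip reproduces exactly this miss).  A per-frame
classification mode is provided additionally (`classify_frames`) but is
not part of the calibrated per-video rule.

## Regressors

A pupil regressor maps a square grayscale crop to continuous normalized
coordinates through average pooling to a g×g intensity grid, per-crop
feature standardization, and a dense ReLU network with a linear
(identity) output head — outputs are not clamped, since out-of-crop
estimates are meaningful inputs to D.  The per-crop standardization
(subtract the crop's pooled mean, divide by its SD) is load-bearing:
pupil position lives in the spatial pattern, and removing per-subject
brightness/contrast keeps residuals uniform across subjects, which is
what the threshold rule implicitly assumes.

Two presets: `tiny` (12×12 pooling, 64/32 hidden units) — the desk-scale
workhorse used in all tests — and `full` (24×24, 256/128/64) for larger
runs.  Training is mini-batch with hand-written RMSprop/Adam/Nadam and the
loss family MAE/MSE/LogCosh/Huber/MAPE/CosineSimilarity; everything is
driven by one seeded generator, so a (config, seed) pair reproduces the
loss trajectory bit-for-bit on a platform.  Defaults follow the
best-performing recipes (cross: RMSprop + MAE, 325 epochs; direct:
Nadam + MAE, 250 epochs; 128-px inputs; labels always trained in [0,1]²
so models are scale-free, errors reported in input-pixel units).  Batch
size defaults to 32 in the synthetic study: the MAE-driven optimizers
need the extra steps per epoch to converge reliably at these sample
counts (larger batches left the cross models' hold-out error 3–4× worse
and seed-sensitive).

The per-sample evaluation error is the squared Euclidean norm of the 2-D
residual ‖P − P̂‖²; reports give its mean (MSE), sample SD, min and max.
An alternative reading — averaging per-coordinate squared differences —
would differ by exactly a factor 2 and is not used.

## Cross-eye dataset construction

Each size-filtered eye pair yields exactly two cross samples: (left crop,
right-pupil target) and (right crop, left-pupil target), targets in the
opposite crop's own normalized frame.  That frame choice is what makes D
well-defined: both estimates of the right pupil live in the right crop's
frame.  Targets come from a trained direct model (the path for
un-annotated data) or from ground truth (strictly better; the default for
synthetic data, where truth is known).  Pairs that never passed the
0.90–1.10 area-ratio filter are rejected with an error — the filter
guarantees the cross target's scale matches the input crop's.

The area-ratio filter is applied symmetrically (both the ratio and its
reciprocal must lie within the inclusive bounds), so acceptance cannot
depend on which eye is the numerator; the effective band on
area_L/area_R is [1/1.1, 1.1].

## The synthetic generator

Crops are rendered as a sclera-level background, concentric antialiased
iris and pupil discs (intensity order pupil < iris < sclera), lids
covering the rows outside a central aperture band, and optional additive
Gaussian pixel noise clipped to [0,1].  Conventions: 0-based pixels, x
right, y down, normalized = pixel/size; crops are not mirrored, nasal is
+x for the left eye and −x for the right, giving eso/exo/hyper/hypo
deviations their signs.  Gaze and deviation are both crop-normalized
pupil offsets from centre, so the rendered offset difference between the
eyes equals the deviation magnitude exactly (and within 1 px after
render-then-centroid recovery).  Shared gaze is N(0, spread), spread
0.06 by default, clipped to ±0.15 so pupils stay inside the aperture.
Deviations can be persistent or confined to an inclusive frame window
(intermittent deviation); with only an active fraction given, a
contiguous window is placed at a seeded random position.

Per-subject appearance (iris radius 0.26–0.36 of crop, pupil 0.32–0.50 of
iris, intensity levels, noise SD 0.01–0.07, aperture 0.68–0.78) is drawn
uniformly per subject and shared by both eyes; ranges are chosen so the
pupil stays fully visible at the maximum gaze-plus-deviation offset.
What the generator does **not** emulate: corneal light reflexes
(Hirschberg glints), eyelashes and blinks, head pose and perspective,
defocus, compression artifacts, skin/face context, and any systematic
asymmetry between a subject's two eyes.  Passing tests therefore show
the method's statistical machinery works when its synchronization premise
holds and eye regions are found reliably — not that a particular detector
or regressor reaches clinical accuracy on photographs.

## The synthetic end-to-end study

`pipeline.run_study` is the package's reference experiment: 3000 normal
training pairs at 64 px (one simulated subject each), tiny-backbone
models (direct 80 epochs, cross 104 — preserving the 250:325 published
epoch ratio; each cross model also sees half the direct model's samples),
ground-truth cross targets, thresholds calibrated on the per-video means
of 20 held-out normal clips of 60 frames, and screening of 20 normal plus
20 deviated test clips (persistent horizontal deviation 0.15 crop-widths
≈ 9.6 px, several times the sub-pixel normal residual; laterality and
eso/exo direction randomized per clip).  Typical results: hold-out direct
MSE ≈ 0.2–0.8 px², cross ≈ 0.7–3 px², sensitivity 1.0, specificity
0.8–1.0 per the operating characteristic above.  The 64-px input size and
these sample counts keep the full study under half a minute on one CPU
while leaving the deviation an order of magnitude above the residuals.

## Numerical and design notes

* SD convention is sample (n−1) everywhere — it is the convention that
  reproduces the published worked example's σ from its six inputs; with
  one unit the SD is reported as 0 rather than NaN.
* Degenerate screening input (no frame passing the size filter) returns
  an explicit `unscreenable` result, never a silent normal; the CLI exits
  nonzero on it.
* Crop squaring expands the shorter box side about the centre; resampling
  is bilinear; an expanded square leaving the frame is an error rather
  than silently padded.
* Rendering with zero noise is bitwise deterministic; all stochastic
  stages (gaze, noise, shuffling, initialization) derive from explicit
  seeds, and dataset/model artifacts carry config + seed + data
  fingerprint provenance.
* The detector is a registry of adapters (frame → named left/right boxes
  or none); the bundled `synthetic` adapter reads ground-truth boxes from
  frame metadata.  A facial-landmark detector can be registered without
  changes elsewhere; none is bundled.
* GI4E-style annotation lines (filename + 12 numbers) are read with a
  configurable point-role mapping, defaulting to the middle point of each
  triplet as the pupil, first triplet = left eye.
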