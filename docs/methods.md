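# Methods

`mupadflow` models and analyses capillary-driven flow on paper-based
microfluidic chips (µPADs) used as astringency sensors: tannic acid (TA)
binds salivary mucin into hydrophobic aggregates that accumulate at the
wetting front, lower the local surface tension, and slow the wicking
rate, so the flow profile encodes the TA concentration.

## Flow model

Capillary imbibition obeys the Lucas–Washburn relation: travel distance
grows with the square root of time, with the rate set by capillary
radius, interfacial tension, contact angle and viscosity.  Those
physical parameters are not separately identifiable from a height trace,
so the pipeline collapses them into a single slope and fits

    ℓ(t) = a·√(t + 1) + b

to each profile, where `t` is in **seconds from the first retained
frame**.  The first second after contact (30 frames at 30 fps) is
discarded as a height reference, which fixes the horizontal shift of the
square-root curve — hence the `+1` inside the root — and leaves only the
vertical offset `b` free.  `a` has units of height per √s (pixels per √s
for unnormalized data) and is the single feature used for
classification.  Fitting in seconds rather than frames keeps `a`'s units
stable across frame rates.

The solver is bounded least squares (`scipy.optimize.curve_fit`) with
`a ≥ 0` (physical monotone imbibition) started from the closed form
`a₀ = (h_T − h₀)/(√(T+1) − 1)`, `b₀ = h₀ − a₀`; the model is linear in
`(a, b)`, so convergence is deterministic and the noiseless optimum is
exact to machine precision.  Non-convergence is flagged, never silently
replaced.

## Front extraction

A recording is reduced to a height series in four steps:

1. **Contact detection** — the first frame is the dry baseline; contact
   is the first frame whose count of ROI pixels differing from the
   baseline by more than `diff_threshold` (default 30 gray levels)
   exceeds `min_wet_pixels_per_row` (default 3).
2. **Front tracking** — per frame, the topmost ROI row with at least
   `min_wet_pixels_per_row` wet pixels.  Frames where the front
   transiently vanishes inherit the previous row rather than reading as
   zero height.
3. **Referencing** — the reference row is a statistic (default: mean;
   median and max-extent are available) of the first 30 post-contact
   rows; heights are `max(0, reference_row − row)` for the remaining
   frames, so a 61-s recording yields 1800 retained values.
4. **Monotone enforcement** — the wetted area cannot shrink, so any
   frame reading lower than its predecessor keeps the previous value
   (a running maximum; idempotent).

Absolute differencing against a single baseline frame makes the heights
invariant to global illumination shifts smaller than the threshold; no
perspective correction or illumination normalization is attempted (the
physical rig fixes the geometry).

## Dataset variants

* **raw** — 126 profiles × 1800 frame heights;
* **mean** — the three simultaneously acquired replicates per
  concentration and session averaged elementwise (42 × 1800), damping
  chip-to-chip fiber and cutting variability;
* **fit coefficient** — one fitted `a` per mean profile (42 × 1), from
  the full 60 s or only the first 15 s.

Frame-feature datasets are min–max scaled **per feature** (each frame
index by its own min/max across samples) before classification;
per-profile scaling is available as an alternative reading of the
protocol.  A constant column (or row) maps to zeros.  Scaling
parameters are computed once on the full dataset, as the study protocol
implies; the resulting train/test leakage under cross-validation is
reproduced deliberately and logged as a warning, not silently fixed.

Averaging always operates on unnormalized pixel heights, and — a design
choice this package makes explicitly — **the square-root fit also runs on
unnormalized heights**.  Per-feature min–max scaling maps every profile
`a_s√(t+1)+b_s` with coincident offsets to the constant
`(a_s−a_min)/(a_max−a_min)`, and per-profile scaling maps every profile
to the identical curve `(√(t+1)−1)/(√(T+1)−1)`: in both cases the fitted
coefficient would be degenerate.  Fitting raw heights keeps `a`
identifiable and lets the noiseless pipeline recover the programmed
coefficients exactly.

## Classification and statistics

Eight classifier families — SVM, multinomial logistic regression
(standing in for the lineup's "linear regression" slot, which cannot
emit classification metrics as an actual regression), MLP, kNN, random
forest, LDA, Gaussian naive Bayes, decision tree — are compared by
exhaustive grid search under stratified, seeded 3-fold cross-validation,
selecting the combination with the highest CV accuracy (ties to the
earlier grid point; no nested CV, so the selection score is the reported
score).  The published hyperparameter ranges are not available; the
package ships modest default grids (e.g. SVM kernel ∈ {linear, rbf},
C ∈ {0.1…100}, γ ∈ {scale, 0.01, 0.1, 1}) declared as defaults, not
reconstructions.  For a selected model, out-of-fold predictions pooled
over the three folds form a single 3×3 confusion matrix from which
per-class and macro precision/recall/F1 are computed; with balanced
classes macro and weighted averages coincide.

Group separation of the fitted coefficients uses one-way fixed-effects
ANOVA plus Tukey's HSD (α = 0.05) and a compact letter display built by
lettering the maximal cliques of the not-significantly-different graph:
groups sharing no letter differ significantly.  When every group has
zero internal variance the F statistic is undefined; the result reports
NaN and assigns letters directly from exact mean (in)equality.

## Synthetic data generator

No study data are deposited, so the generator emulates the acquisition:
14 sessions × 3 concentrations (0.1/0.5/1.0 g/L) × 3 replicates = 126
profiles of 1800 retained frames (61 s at 30 fps minus the 30-frame
reference).  Per class, coefficients are drawn as
`a ~ N(mean_a, sd_a)` truncated positive and `b ~ N(mean_b, sd_b)`;
heights follow the exact square-root law plus i.i.d. Gaussian
measurement noise, clipped at zero and quantized to integer pixels —
which reproduces the non-monotone raw series the carry-forward rule
exists for.  Defaults: class means 60/45/30 px/√s (decreasing with
concentration, ≥3 within-class s.d. apart at sd_a = 3), b ~ N(0, 2 px),
noise 2 px.  The magnitudes follow from the chip geometry (≈29 mm of
usable run imaged at ≈17 px/mm); they are synthetic choices, since the
study prints no coefficient or noise values, and the coefficient-scale
outputs therefore cannot be compared numerically to the published
distributions.

The renderer draws the strip as a column band with the wet region
spanning from the baseline row up to `baseline_row − round(h)`, prepends
dry pre-contact padding frames (default 15) and holds the front at the
baseline row during the reference second, so the extractor's reference
equals the baseline and a noiseless render→extract round trip is exact
up to the 1-px quantization bound.  Real recordings differ in ways the
generator does not model — perspective, uneven illumination, fiber
texture, front curvature, immersion-depth transients — so passing tests
demonstrate the correctness of the computational chain, not field
performance of the sensor.

Because the default class separation is wide (≈5 within-class s.d.),
cross-validated accuracies on clean synthetic data sit at or near 1.0
for most families; the interesting guarantees are the relative ones
(coefficient features match or beat raw frame features at matched noise,
shuffled labels fall to chance, Tukey letters separate all three
classes).

## Numerical and design notes

* Determinism: every random stage draws from `numpy` generators spawned
  from a single root seed; identical (design, model, seed) gives bitwise
  identical artifacts.
* Windowed fits (`15 s` vs `60 s`) coincide exactly on noiseless data;
  they drift apart only under noise or early-time disturbances, which is
  the behaviour the truncated-window comparison probes.
* Degenerate inputs: constant profiles fit `a = 0, b = h`; constant
  columns normalize to zero; empty ROIs, too-short windows, fronts
  leaving the frame and unknown class labels raise typed errors.
* Problem sizes in the shipped tests and the acceptance script use the
  full 126 × 1800 study design for dataset, fitting and classification
  stages, and a spatially scaled-down frame (320 × 80 px) for full-length
  rendering round trips, keeping the rendered stacks small while
  preserving the 61-s timeline.

## Known limitations

* One strip per ROI and per video; multi-strip scenes need one ROI each.
* MP4/AVI decoding requires an imageio ffmpeg plugin; PNG frame
  directories always work.
* The deliberate dataset-wide normalization leakage means CV accuracies
  are optimistic relative to a strictly fold-wise protocol.
* The generator's noise is i.i.d. Gaussian per frame; real front
  measurements have autocorrelated errors, so noise-robustness results
  transfer qualitatively, not quantitatively.
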