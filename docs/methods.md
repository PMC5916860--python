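# Methods

This note records the models, conventions and numerical choices behind
`leafdyn`, in the spirit of a statistics-package methods appendix.  It
states nothing that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The measurement model

One observation is one leaf scanned flat on a near-white background at a
known resolution.  Pixel measurements are calibrated with
1 px = 2.54/dpi cm.  Four leaf positions are tracked per plant: the first
incomplete leaf (FIL; newest, still expanding) and the 1st–3rd fully
expanded leaves, counted from the top.  Nitrogen status expresses itself
at the two ends of this ladder: blade *expansion* (area/perimeter growth)
in the FIL, and *etiolation* — tip-first yellowing — in the 3rd (oldest
scanned) leaf, from which nitrogen is remobilized first.

### Shape characteristics

* `LA` (cm²): pixel count of the segmented blade × (2.54/dpi)².
* `LP` (cm): length of the 0.5-level marching-squares iso-contour of the
  blade mask, after smoothing the binary mask with a Gaussian of σ = 0.8 px.
  The smoothing is part of the estimator: the raw iso-contour of a
  rasterized shape carries an orientation-dependent staircase excess (a
  rasterized disk reads ≈ 6% long; across re-rendered blade rotations the
  raw estimate varies by ≈ 4%), while the smoothed contour tracks closed
  forms for squares and disks to under 1% and is rotation-stable to ≈ 0.7%.
* `EA` (cm²), `ED = EA/LA` ∈ [0, 1]: area and areal fraction of the
  etiolated (yellowed) part, scored on the 3rd leaf only.

### Colour characteristics

Colour is summarized by the region-mean RGB (mean-then-index; a per-pixel
averaging switch exists but the mean-then-index convention is the default
because it is stable under pixel noise).  The region is the whole blade
for the FIL — its colour is close to uniform — and the distal third of
the long axis for expanded leaves, whose tip responds to nitrogen first.
Indices: `G` (mean green channel), `NRI/NGI/NBI` (channel shares of
R+G+B, which always sum to 1), `ExR = 1.4·NRI − NGI`,
`ExG = 2·NGI − NRI − NBI` (equivalently `3·NGI − 1`), and
`DGCI = [(Hue−60°)/60 + (1−S) + (1−B)]/3` with HSV hue in degrees,
red = 0°.  DGCI is left unclamped (negative below hue 60°) and is
undefined — reported missing — for near-achromatic colour (S < 0.05).
`NGI` and `NBI` are defined by analogy with `NRI`, the standard usage in
the colour-index literature.

### Segmentation conventions

* Background: the modal background colour is the per-channel median of
  the image border; pixels whose Euclidean RGB distance from it exceeds a
  threshold (Otsu on the distance image by default; a fixed distance is
  configurable) are candidate leaf.  Largest connected component, holes
  filled.  A minimum-size floor rejects noise specks: 100 px at the
  reference 300 dpi, scaled by (dpi/300)² so that a sub-cm² young FIL
  survives at lower resolutions.
* Etiolation: leaf pixels with HSV hue in [0°, 75°) — the yellow side of
  green — and S ≥ 0.05.  The 75° cut is configurable; it is a stand-in
  convention, since yellowing thresholds are not standardized.
* Tip third: pixels whose projection on the mask's first principal axis
  falls in the distal third of the axis extent.  The tip end is the end
  with the smaller mean transverse width over the outer 10% of the axis;
  for masks with aspect ratio < 1.2 the choice is ambiguous, a warning is
  raised, and the end with the greater axis coordinate is used.  The
  divider is pixel-quantized: at 60 dpi it can shift the selected area by
  ≈ 1% of the blade, which is why colour-fidelity tests run at ≥ 100 dpi.

## 2. Dynamic characteristics

Shape is quantified by the relative growth rate
`RGR = (ln W₂ − ln W₁)/(t₂ − t₁)` (per day) and colour by the average
changing rate `ACR = (X₂ − X₁)/(t₂ − t₁)` (index units per day).  RGR is
scale-free (unit changes cancel) and additive over abutting periods in
the duration-weighted sense; both properties are enforced as tests.

Periods on the DAT 20…44 schedule: 3-day spacing gives consecutive pairs
P1 = (20, 23) … P8 = (41, 44) sharing endpoints; 6-day spacing gives
non-overlapping pairs P1′ = (20, 26) … P4′ = (38, 44).  The final period
of each spacing is excluded by default (`drop_final`), modelling the loss
of late observations to old-leaf senescence; this yields the working
counts of 7 three-day and 3 six-day data sets.  A period cell exists only
when both endpoint observations exist; RGR cells additionally require
positive endpoints (EA = 0 before etiolation onset leaves `RGR_EA`
undefined — recorded missing rather than epsilon-padded, because any
epsilon would dominate the logarithm).

### Growth-pattern fitting

Replicate-mean LA and LP trajectories are fitted by nonlinear least
squares under three laws — power `a·tᵇ`, exponential `a·e^{bt}`,
sigmoidal logistic `A/(1+e^{−k(t−t₀)})` — from a documented multi-start
grid (log-linear regression seeds for power/exponential; an
A × k × t₀ grid for the logistic), keeping the best-RSS convergent fit.
Models are compared by R² and the SPSS-style `AIC = n·ln(RSS/n) + 2p`
(p = number of parameters; RSS = 0 reports −∞); lower AIC wins, ties go
to the simpler model.  On the 9-point schedule the sampling sd of k is
≈ 2.8% per 1% of observation noise, so parameter-recovery checks are run
at 2% noise, where A is recovered within 5% and k within 10% in well over
80% of replicates; at 5% noise that band is statistically unattainable
regardless of optimizer.

## 3. Screening

Classical equal-variance one-way ANOVA per dynamic characteristic × leaf
position × period, across the four treatments; each plant-period cell is
one observation and years are pooled.  Missing cells are dropped per
feature; groups left with fewer than two values are excluded with the
degrees of freedom adjusted.  Degenerate inputs resolve by convention:
all values identical → F = 0, p = 1; zero within-group variance with real
between-group spread → p = 0 with a flag.  Significance is raw p < 0.05
(no multiplicity correction — the screen is exploratory; Benjamini–
Hochberg is available behind a flag).  At df (3, 30) the 5% boundary is
F = 2.92.

## 4. Diagnosis

A modelling dataset concatenates, per plant, the dynamic feature columns
of the selected leaf position(s) and period(s) in time order (columns
`feature|position|period`).  Columns that are missing for every plant are
removed; remaining rows with any missing cell are dropped and counted —
never imputed, mirroring the missing-cell policy above.

Classifier: one-vs-one soft-margin SVM with RBF kernel, C = 1.  The
kernel width defaults to the variance-aware `γ = 1/(n_features·Var(X))`:
with min-max scaling to [0, 1] and the near-constant ACR columns that a
constant-colour leaf produces, the plain `γ = 1/n_features` kernel is so
flat that leave-one-out prediction on four ordinal classes collapses
(every held-out plant lands in an adjacent class); the plain variant
remains selectable.  Feature scaling and the optional coarse
(C, γ) grid search are computed inside each training fold only, so the
held-out row never leaks into scaling statistics — asserted in the tests
by comparison with an independent pipeline re-implementation.

"Training accuracy" is resubstitution accuracy of the model fitted on all
rows; "validation accuracy" is leave-one-out cross-validation, the
small-sample standard for cohorts of ~20–40 plants.  Note that under
label permutation LOOCV sits slightly *below* the 1/k chance level
(≈ 0.19–0.21 against 0.25 here): removing the held-out sample makes its
class the training minority, a known small-sample artifact.  The
evaluation grid covers every single period, every cumulative time-ordered
combination (P1+P2, P1+P2+P3, …), each leaf position separately and the
FIL + 3rd combination, for both spacings.

## 5. The synthetic-data generator

The generator emulates the statistical structure of a two-season
hydroponic glasshouse trial with a single cultivar: 4 ammonium-nitrate
levels (0, 57.20, 85.70, 114.30 mg/L) × 5 replicate plants × scans every
3 days (DAT 20–44) × 4 leaf positions, at a configurable resolution.

* **Blade geometry**: a symmetric lanceolate outline with half-width
  profile (w/2)·sin(π·s^0.75) along the normalized axis s ∈ [0, 1]
  (s = 1 at the tip); the exponent < 1 places the widest point toward the
  base so the tip is geometrically identifiable.  Length and width are
  solved from the target area under a fixed length:width ratio (default
  12:1, scaled per treatment — deficient leaves are narrower).
* **Expansion**: blade area follows `A/(1+e^{−k(t−t₀)})`; A and k
  increase with nitrogen (defaults: A = 12→26 cm², k = 0.35→0.55 /day for
  N1→N4), with per-position offsets (older leaves emerged earlier and are
  smaller).
* **Colour**: healthy RGB from (90, 140, 60) for N1 down to (60, 120, 40)
  for N4 — greener with more nitrogen; 3rd-leaf healthy tissue drifts
  slowly toward olive with age.  Etiolated tissue is scanner-yellow
  (hue ≈ 52°).
* **Etiolation**: on the 3rd leaf a transverse front at fractional
  distance `clamp(front_speed·(t − onset), 0, 1)` from the tip; the
  green/yellow edge is hard, softened by a 1-px Gaussian blur of the
  colour weight only (the blade outline stays crisp so shape extraction
  is not confounded).  Onsets precede DAT 20 (14–19 d) and front speeds
  fall from 0.030 to 0.010 of leaf length per day for N1→N4, so every
  3rd-leaf observation carries a nonzero etiolated area and deficient
  plants yellow visibly faster.
* **Missingness**: the 3rd leaf is recorded missing after its senescence
  day (N1 at DAT 41, N2 at DAT 43, none for N3/N4) — whole observations
  disappear, never partial images.
* **Variability and noise**: replicate plants draw lognormal
  multiplicative noise around treatment means — CV 10% on size and rate
  parameters, CV/5 on timing (t₀, onset) and CV/3 on colour, since
  replicates of one cultivar in a controlled glasshouse vary far more in
  size than in developmental timing; additive Gaussian pixel noise
  (σ = 2) on the rendered image.  An `effect` dial interpolates all
  treatment profiles toward their common mean (effect 0 = null condition)
  for calibration experiments.
* **Ground truth** is computed from the rendered masks with the same
  perimeter convention as the extractor, so oracle comparisons isolate
  extraction error; the analytic polygon perimeter is reported alongside.
  A quadrature-based fast path (`simulate_features`) produces the same
  feature table without rasterizing, for power analyses where rendering
  would dominate runtime; the rendered path remains the reference.

What the generator does **not** emulate: leaf texture and venation,
specular scanner artifacts, 3-D curvature, illumination gradients,
multi-leaf scenes, and real biological covariance between shape and
colour beyond the shared treatment effect.  Passing tests therefore
demonstrate the correctness and calibration of the *pipeline*, not field
performance on real scans.

## 6. Problem sizes and determinism

Real scans are expected at ~300 dpi; the test suite and the acceptance
script render at 35–100 dpi, which keeps a full cohort render in seconds
while remaining resolution-honest (all oracle comparisons are against
truth computed from the same rendered masks).  Every random draw descends
from one master seed through `numpy` seed sequences; per-observation
noise streams are keyed by (plant seed, DAT, position), so any
observation can be re-rendered in isolation.  Pipeline outputs are
written with fixed row ordering and float formatting, and a manifest
records a SHA-256 hash per artifact; two runs with the same seed are
byte-identical.

## 7. Known limitations

* The hue-threshold etiolation rule ignores chlorosis that expresses as
  pale green before turning yellow; `ED` is a lower bound in that regime.
* The tip-third divider is pixel-quantized; below ~50 dpi its placement
  error is no longer negligible for colour means on short leaves.
* LOOCV accuracies on 20-plant cohorts have wide sampling bands (±0.1 is
  one held-out plant); the evaluation grid reports them per data set
  without interval estimates.
* AIC defaults to the residual-sum-of-squares form without the
  small-sample correction, matching common statistics-package output;
  with n = 9 points per trajectory, the selectable AICc variant
  (`use_aicc`) penalizes the 3-parameter logistic more strongly.
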