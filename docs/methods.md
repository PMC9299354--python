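# Methods

This note documents the models, conventions and numerical choices behind
`cervitrace`, and what the synthetic validation does and does not establish
about real clinical recordings.

## The measurement model

A laser pointer is fixed to the head; the subject traces a 1 mm black line
folded into a zigzag of total path length 1000 mm, printed on an A3 board
viewed by a static consumer camera from an oblique position. Twelve trials
are performed (three in each of four directions: left→right, right→left,
up→down, down→up; the vertical directions use the pattern rotated 90°).

All quantitative claims (mm distances, mm/s speeds) rest on a single planar
homography per trial: the board is planar and static, so four point
correspondences — the corner fiducials — determine the pixel→mm projective
map exactly. We deliberately do not model lens distortion or camera
intrinsics; for consumer cameras at the working distance the residual
non-projectivity is far below the millimetre tolerances that matter here.

### Coordinate conventions

Pattern frame: origin at the top-left board corner, x right, y down,
units mm. A3 landscape is 420 × 297 mm; the vertical pattern is the 90°
rotation of the horizontal one about the board centre (board transposed).
Pixel frame: origin top-left, x right, y down.

### Zigzag geometry

The published description fixes only the path length (1000 mm), line width
(1 mm) and paper size; the fold geometry is not dimensioned. We default to
5 peaks (10 segments) spanning the board width minus 20 mm margins, with
the peak amplitude solved so the segment lengths sum to exactly 1000 mm
(amplitude ≈ 92.5 mm peak-to-peak). Everything is configurable; an
`amplitude_mm=0` degenerate pattern gives a straight 1000 mm line, which is
useful because several closed-form results are exact only there (see
below).

## Image pipeline

**Corner fiducials.** The rendered (and expected physical) board carries
filled dark squares centred on its corners. Detection thresholds dark
pixels and keeps compact connected components (extent = area / bounding box
≥ 0.45), which cleanly rejects the equally dark but thin target line. The
four largest candidates are ordered TL, TR, BR, BL by angle about their
centroid, anchored at the point with minimal x + y. The homography is
estimated once per trial from the median corner positions over the first 30
frames; per-frame jitter is thereby suppressed.

**Laser dot.** Per frame, candidate pixels satisfy red-channel intensity
≥ 150 and redness (R − max(G, B)) ≥ 40; connected components within 3–500
px² compete on an intensity × redness score, which rejects achromatic
specular glare of similar brightness. The centroid is intensity-weighted; a
frame with no acceptable blob yields a *missing* sample (a value, not an
error — the dot routinely drops out when crossing the dark line). Gaps of
at most 5 frames are filled by linear interpolation and flagged; a trial
with more than 10% missing samples inside the trial window after filling
fails QC (flagged, never silently dropped).

**Trial segmentation.** The recording software has to decide when a trial
starts and ends; no published rule exists, so ours is explicit and
configurable: the trial starts at the first sample where the dot, having
dwelt ≥ 0.5 s within 15 mm of the start vertex, exceeds 10 mm/s; the
approach to the far end is flagged when the dot enters the same radius
around the end vertex, and the trial ends at the first local minimum of the
distance to the end vertex (2 mm hysteresis). Ending on radius *entry*
instead would truncate every trial by radius/speed seconds (0.3 s at
50 mm/s) — a systematic bias the local-minimum rule avoids; on noiseless
synthetic trials both endpoints are recovered to within one frame.

## Outcome variables

* **Time** = t_end − t_start (s).
* **Acuity** = 100 × (in-window samples within tolerance of the centerline)
  / (in-window non-missing samples). Sampling is uniform in time, so the
  sample fraction estimates the time fraction; at 25 fps the discretisation
  error is below one percentage point for 20–40 s trials. Interpolated
  samples count; missing samples are excluded from numerator and
  denominator alike.
* **Speed** = summed frame-to-frame mm displacement in the window divided
  by window duration. Note that measurement noise and physiological tremor
  add real path length, so Speed is an upper estimate of the along-path
  speed; this is a property of the measure itself, not of this
  implementation.
* **NormAcuity** = Acuity / Time, computed **per trial** and then pooled.
  Pooling the ratio of pooled means instead would give a different (and
  wrong) number whenever Acuity and Time covary across trials.

**On-line tolerance.** "On the line" is an overlap statement between a
printed line of physical width and a laser dot of physical extent. The
default tolerance is line half-width + detected dot radius (the dot radius
in mm comes from the median detected blob radius through the homography
scale, ≈ 2.5–3 mm with the default rendering); a fixed tolerance can be
configured. Observed clinical acuities in the 55–67% range are consistent
with an effective tolerance of a few millimetres.

**Pooling** is the grand mean over the 12 QC-passing trials; with the
balanced 3 × 4 design this equals the mean of direction means. A direction
with zero usable trials is an explicit pooling error, because the grand
mean would then silently change its meaning.

## Statistical battery

* **Normality gate**: Shapiro–Wilk at α = 0.05 on pooled group-mean
  residuals (per variable). Gated variables are Ln-transformed for the
  inferential statistics; descriptive tables always report untransformed
  values; SEM is always computed untransformed so it keeps the variable's
  units.
* **ANOVA**: one-way fixed effects across CON/INP/TNP; post-hoc pairwise
  pooled-variance t tests with Bonferroni factor 3 (adjusted p capped at
  1). The effect size is eta-squared (between-group SS / total SS).
* **ROC**: AUC via the rank-sum (Mann–Whitney) formulation with midranks
  for ties; the p value uses the tie-corrected normal approximation to U.
  Patients have *lower* NormAcuity, so the score axis is negated: the 2.5
  %·s⁻¹ cutoff classifies "case if NormAcuity < 2.5". Sensitivity and
  1−specificity at the cutoff are simple fractions on each side.
* **ICC(2,k)**: two-way random effects, absolute agreement, average
  measures, from the mean squares of the subjects × occasions ANOVA
  decomposition. The 95% CI uses the F-based interval with Satterthwaite
  degrees of freedom on the single-measure form, stepped up to k measures
  by Spearman–Brown, clipped to [−1, 1]. Duplicated occasions give exactly
  1 (the error mean square is computed from cell residuals, which vanish
  identically in that case). Band labels: < 0.5 poor, 0.5–0.75 moderate,
  0.75–0.90 good, > 0.90 excellent, 1 perfect.
* **SEM / MDC**: SEM = SD(d)/√2 with the n−1 SD of the paired differences;
  MDC = SEM × 1.96 × √2 (= 2.7719 SEM). A constant test-retest shift is
  pure systematic bias and correctly yields SEM = 0.

## Synthetic ground truth

**Trajectories** move along the centerline arc-length parameterisation at a
constant or cosine-ramped speed profile after a scripted dwell, with
Gaussian lateral error of SD σ applied perpendicular to the local path
direction (i.i.d. by default; an AR(1) option with stationary marginal SD σ
models tremor smoothness). Defaults: 20 s traverse, 25 fps, σ = 1.5 mm — a
realistic laser-jitter scale at the 100 cm working distance.

**Closed-form acuity.** With tolerance τ, the expected acuity is
100·(2Φ(τ/σ) − 1). This is *exact* when the distance to the centerline
equals the absolute lateral offset, i.e. on straight segments. Near zigzag
vertices the polyline distance can undercut the offset (the adjacent
segment is closer — "corner cutting"), so on the default folded pattern the
measured acuity sits *above* the closed form: numerically ≈ +1.2 percentage
points at σ = τ = 1.5 mm with the default 44.6° vertex angles. The
closed-form validation therefore runs on the straight degenerate pattern,
where it is the exact expectation; the zigzag bias is covered by a
one-sided test.

**Rendering** rasterises the static scene once (grey wall, white board,
dark line, corner fiducials) by mapping every pixel through the inverse of
a known mm→px homography built from an oblique pinhole pose (default 20°
pitch/yaw, 720p, rescaled so the board fills the view), then composites a
Gaussian red dot per frame; optional sensor noise and achromatic glare
blobs stress the detector. Ground-truth corner and dot pixel positions are
exported with the frames.

**Cohorts** draw subject true scores per outcome from Normal(group mean,
between-SD); observed scores add Normal(0, within-SD) occasion error and a
systematic occasion-2 learning shift (defaults: Speed +10 mm/s, Time
−3.5 s, NormAcuity +0.4, Acuity 0). NDI is drawn jointly with the Acuity
true score as a bivariate normal at the configured correlation, clipped to
[0, 100]. With k occasions the implied ICC(2,k) is σ_b²/(σ_b² + σ_e²/k),
which the estimator recovers (mean over 500 cohorts within 0.02), and the
SEM estimator recovers the generating within-SD. Group-level defaults
follow the published descriptives of the clinical population (per-group
means and SDs, NDI models, test-retest SEMs as within-SDs).

## What the synthetic validation does not show

The renderer is not photorealistic: no motion blur, rolling shutter, lens
distortion, lighting gradients, or occlusion of the board by the subject;
the lateral-error model is stationary Gaussian, whereas real head tremor is
likely non-stationary and direction-dependent. Passing the end-to-end
checks therefore demonstrates the correctness of the geometry, tracking and
scoring logic under the stated imaging model — not detector robustness on
arbitrary clinic footage. The cohort generator treats the four outcomes as
(nearly) independent Gaussians per subject, whereas real outcomes are
mechanically coupled (NormAcuity is literally Acuity/Time); it is a tool
for validating the statistical estimators at known variance components, not
a physiological model.

## Problem sizes

Default validation sizes: 640 × 360 rendering for unit tests and 1280 × 720
for the end-to-end check (526 frames); 200 simulated trials for the
closed-form acuity law; 500 simulated cohorts (n = 50, k = 2) for
variance-component recovery; ~9000 small score/label sets for the AUC
oracle equivalence. These sizes give Monte-Carlo CIs comfortably inside the
assertion tolerances while keeping the whole suite fast on a laptop.
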