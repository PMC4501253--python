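# Methods

## Measurement model

The analysis object is a per-patient stack of closed endocardial contours
(frames × slices × boundary points, mm) with per-frame long-axis landmarks
(mitral annulus centre and apex). All quantities derive from radial
displacement about a translation-corrected centroid:

1. **Centroid correction.** On every frame the LV long axis is the line from
   the mitral centre to the apex; each slice's centroid is the axis point at
   that slice's long-axis position. A rigid whole-heart translation moves the
   landmarks and therefore every centroid identically, so displacement curves
   are invariant to translation by construction (verified to < 1 ms effect on
   the delay map).
2. **Resampling.** Each contour is intersected with 100 rays at equal angles
   about the slice centroid; intersections are exact ray/edge solutions
   (arc-length-parameterized linear interpolation along the boundary), so
   input point counts and point phases are arbitrary. A slice whose centroid
   falls outside the contour (winding test) is marked invalid.
3. **Displacement.** d(t) = r(0) − r(t), inward positive, zero at the first
   frame (taken as end-diastole/R-wave).
4. **Delay estimation.** Each site's curve is cross-correlated with the
   patient-specific reference curve at integer lags within ± half a cycle
   (delays near a full cycle are aliased); correlations are Pearson
   coefficients over the overlapping window. The discrete peak is refined by
   parabolic interpolation through its two neighbours, except when the peak
   correlation is exactly 1 (an exact alignment needs no refinement). Ties
   resolve toward the smaller |lag|; zero-variance curves carry no delay.

### Angle and segment conventions

θ = 0° at the anterior junction of the RV free wall with the septum,
increasing counterclockwise viewed from the apex; the septum spans
[240°, 360°). Sector intervals are half-open [lo, hi). Slices partition into
basal/mid/apical thirds, remainder assigned basal-first (basal slices are
anatomically longest); basal and mid rings carry the standard six 60° AHA
sectors and the apical ring four 90° sectors at [0°, 90°), [90°, 180°),
[180°, 270°), [270°, 360°). Each apical sector is adjacent to the two mid
sectors it overlaps (one fully, one by 30°); within rings adjacency is
circumferential, and basal sectors adjoin the mid sector directly below.
Segment 17 (apical cap) carries no short-axis sites and is excluded.

### Reference curve

The source method's reference-curve construction is not specified; this
package uses the pointwise mean of all valid site curves — deterministic,
self-consistent, and independent of segment labels. A septal-mean reference is
available via `AnalysisConfig(reference="septal")`.

### Pattern classification

Per-segment delay is the median over its valid sites (robust to residual
passive sites). "Early" and "late" segments are those within the lowest and
highest third of the observed delay *range*. Value terciles rather than count
terciles are deliberate: when scarred or akinetic segments drop out, count
terciles shift membership and can promote a mid-gradient segment into the
late set, manufacturing a spurious early/late adjacency; value terciles are
invariant to segment dropout. A block edge is an adjacent early/late pair
differing by ≥ `block_threshold_ms` (default 100 ms); type II iff ≥ 1 block
edge. A delay range below the threshold is flagged homogeneous (type I). The
qualitative published definition ("adjacent early and late segments") carries
no quantitative cut, so the 100 ms default is this package's documented
substitute, not an authors' value. Raising the threshold can only remove block
edges, so a type I call never becomes type II (tested).

### Septal flash and the latest contracting site

Septal flash = within the isovolumic-contraction window, an inward excursion
of ≥ 10 % of the site's end-diastolic radius followed by a return toward
baseline of at least half that excursion, in ≥ half the valid sites of at
least one septal segment (2, 3, 8, 9, 14). When aortic-valve timing is
unavailable the IVC window defaults to the first 80 ms of the cycle
(long-axis valve cines are out of scope; the window is configurable). In
flash segments, time-to-peak is the first local displacement maximum at or
after motion onset rather than the later global (rebound) peak. The latest
contracting site is the valid site with maximum (flash-adjusted) time to
peak, refined sub-frame by parabolic interpolation; exact ties resolve to the
smaller slice, then site index. Maximum wall delay defaults to the largest
|delay difference| between diametrically opposed sectors within a ring
("opposing" mode); a global range mode is exposed because the published table
row is ambiguous between the two.

### Lead localization and T2CL

Fluoroscopic projection geometry is not modelled: the two-view reading
reduces to a long-axis fraction (RAO) selecting the ring by thirds and a
circumferential angle (LAO) selecting the sector, or a direct segment id.
Concordant = viable segment within one segment (full adjacency table,
cross-ring neighbours included) of the latest contracting segment; a lead
segment with > 50 % transmural scar is remote regardless of proximity.
T2CL = type II AND concordant.

## Synthetic data generator

Site radius follows

    r(s, θ, t) = R0(s) − A·(1 − scar_s)·g(t − τ(s, θ)) − flash(t) + ε

with g a raised-cosine rise (default 330 ms) to 1 followed by a raised-cosine
relaxation (400 ms) — smooth, unimodal, differentiable; the flash term an
early inward sin² pulse (12 % of local radius over the 0–80 ms window) in
flash segments; rigid in-plane translation applied to contours and landmarks
jointly; and iid radial Gaussian noise. Defaults emulate a typical cine
acquisition: 30 frames × 33 ms, nine 8 mm slices, 100 points/contour, basal
radius tapering 28 → 14 mm, 8 mm contraction amplitude. Within a ring, site
delays interpolate linearly between sector-centre values except across
declared block edges, where the discontinuity is preserved — this produces
the line-of-block signature the classifier must detect.

Activation templates: *type I* is a linear delay gradient in angular distance
from the mid-septum (default 40 + 350·dist/165° ms, matching a large but
homogeneous septal-lateral delay); *type II* is a breakout at the
inferoseptum (or anteroseptum) sweeping around the free wall at 1.25 ms/deg so
the opposite wall activates last across a ~375 ms line of block, with a
+30 ms bump on the mid latest segment to make the latest site unique.
Cohort-level covariates (pattern, concordance, NICM, ECG, flash, scar, max
wall delay) are drawn at the 33-patient study's stratum rates, and response
follows a logistic model whose defaults give a non-T2CL response odds of 0.5
and a T2CL odds ratio of 22; ESV follow-up is drawn consistent with the
response label and the ≥ 15 % rule.

What the generator does *not* emulate: pixel-level image formation and
segmentation error, through-plane motion, regional waveform-shape variation
beyond timing/amplitude, breathing drift, and arrhythmic cycle-length
variability. Passing round-trip tests therefore demonstrates correctness of
the measurement chain, not robustness to segmentation quality in real CMR.

## Validation quantities and problem sizes

- Delay recovery: noise-free patients of each template; error after
  best-constant alignment (delays are identified only up to the reference
  origin; the cross-correlation estimator has a small one-sided truncation
  bias at extreme lags, so the max-residual-minimizing constant is used).
  Observed ≤ ~11 ms against a 16.5 ms (half-frame) bound; pure time-shifted
  curves recover within 5 ms (0.15 frame).
- Pattern classification: 200 patients at 0.5 mm noise mixed at the study's
  13:20 pattern ratio with study-rate flash/scar/block strata.
- Latest-segment recovery: 40 noise-free patients, 100 % required.
- Multivariate CI coverage and AUC-increment power: 200 replications of
  n = 330 cohorts with a true multivariate T2CL effect (OR 18 alongside NICM
  and ECG terms); these stand in for the published multivariate OR, AUC
  increment and kappa values, whose patient-level joint data were never
  published.
- Fisher's exact test: exhaustively compared with an independent exact
  enumeration oracle on all 135,750 tables with total ≤ 40.

## Numerical choices and degenerate inputs

Fisher's test uses exact integer arithmetic over the hypergeometric support
(point-probability two-sided rule — the convention that reproduces the
published p-values; zero margin → p = 1, flagged). The t-test is the
pooled-variance Student form (df = n₁+n₂−2), matching the published 0.016;
Welch is an option. Logistic CIs are Wald (the era's default software
output); |coefficient| > 15 on the logit scale flags separation and marks
CIs unreliable. Odds-ratio rounding for table reproduction is two significant
figures half-up (5.25 → 5.3), p-values to the printed decimals. Monotone
displacement curves with no interior peak report the last frame's time.
Degenerate 2×2 margins, all-equal outcomes, single-category kappa and empty
masks raise typed errors rather than returning silently.

## Known limitations

- The ESV-by-response and age rows of the published baseline table are not
  reproducible from their printed summaries by a pooled t-test (the original
  likely used Mann–Whitney for skewed variables); they are packaged but not
  checked.
- The published multivariate OR (18), AUC increment (0.69 → 0.84) and kappa
  values cannot be recomputed exactly without patient-level data; they are
  validated by the property-based experiments above instead.
- Delay maps are reported relative to the patient-specific reference; no
  absolute electrical timing is implied.
- The contour resampler assumes star-shaped contours about the centroid
  (true for endocardial borders in practice); strongly non-convex shapes
  would need a different parameterization.
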