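# Methods

## Problem and data model

The package models the monitor phase of a bolus-tracked multiphase hepatic
CT examination: a single axial slice at a fixed table position, imaged
repeatedly at a fixed interscan interval while intravenous contrast
arrives in the abdominal aorta.  The in-memory object is an `ImageSeries` —
a `(n_frames, rows, cols)` stack in Hounsfield units (HU) with an isotropic
in-plane pixel spacing (default 0.82 mm/pixel), an interscan time (default
3 s), and a slice thickness carried as metadata only (nothing is computed
through-plane).  Coordinates are 0-based `(row, col)`; the row axis is
mapped to the anterior–posterior (AP) direction and the column axis to the
lateral (LAT) direction of the axial plane, with displacement positive
toward increasing index.  This is a declared convention: displacement sign
is only meaningful once an axis convention is fixed, and fixing it makes
every sign testable.

Vessel delineations are `RoiMask` objects — explicit sets of integer pixel
coordinates.  The ROI area is `count × spacing²` exactly; masks are
consumed, not produced (automatic segmentation is out of scope).

## Barycenter tracking

The vessel-section barycenter is the arithmetic mean of the member pixel
coordinates, kept at sub-pixel precision.  Frame-to-frame displacement is
the difference of successive barycenters; the reported "movement" is the
per-step Euclidean magnitude (matching per-estimation statistics, not
cumulative path length, which is available separately).  Two numerical
notes:

* barycenter translation equivariance is exact only to one ulp of the
  double-precision mean (`(S + tn)/n` and `S/n + t` can round differently);
  tests assert it at 1e-12;
* trajectory displacements telescope exactly because they are defined as
  differences of the stored barycenters.

## Horn–Schunck optical flow

The dense motion vector field between consecutive frames combines the
brightness-constancy gradient constraint with a global smoothness penalty
weighted by α, solved by the classic Jacobi-style iteration from a zero
initial field.  Defaults are α = 5 on raw-HU intensities and a fixed 100
iterations.  Choices:

* **Local average**: the original weighted 8-neighbour stencil
  (4-neighbours 1/6, diagonals 1/12); a plain 4-neighbour mean is available.
* **Derivatives**: averaged forward differences over the 2×2×2 space–time
  cube (the original estimator); central differences on the frame average
  are available.  Both use edge replication, which avoids spurious boundary
  flow from zero padding.
* **Input intensities**: raw HU by default.  α = 5 is calibrated against
  HU-scale gradients; running the solver on display-windowed images
  ([0, 1] scale) starves the data term against α² = 25 and collapses the
  field (measured recovery < 0.02 of truth), so windowed input is a
  sensitivity option (`windowed_flow`), not the default.
* **Stopping**: fixed iteration count (deterministic, bit-reproducible); an
  optional mean-update tolerance can stop early only when explicitly set.
* **Single resolution**: no pyramid.  Displacements beyond the
  linearisation range of the gradient constraint are systematically
  underestimated; see *Known limitations*.

Units follow a typed progression: pixels/frame → mm (× pixel spacing) →
mm/s (÷ interscan time); applying a conversion in the wrong state raises a
unit error, so pixel-scale values cannot leak into physical reports.

Per-ROI reduction takes the mean of each component over the ROI pixels;
the scalar movement is the norm of that mean vector by default
(`norm-of-mean`), with `mean-of-norms` selectable.  The norm-of-mean is
the displacement of the ROI as a rigid body and cancels antisymmetric
deformation; the mean-of-norms is larger under incoherent motion.

## Bolus tracking and motion correction

The enhancement curve is the per-frame arithmetic mean HU over the ROI;
the trigger fires at the first frame whose mean **reaches** the threshold
(≥, default 130 HU).  Indices are 0-based in the API and 1-based in
console reports.  Motion-corrected tracking propagates the frame-0 ROI: per
frame pair the flow field is estimated, reduced over the current ROI,
rounded to the nearest integer offset (ties toward zero), and the ROI is
hard-shifted (no interpolation, so pixel count — hence area — is invariant
while in bounds).  Rounding rather than sub-pixel resampling keeps the
measured ROI statistics exactly comparable across frames.

The corrected tracker is reliable where the per-pair flow estimate rounds
to the true step: small vessel sections (radius ≲ 7 mm) and steps around
1 px.  For large homogeneous sections the ROI-mean flow underestimates
(below), the rounded offset can be 0, and the ROI lags; the pipeline logs a
warning for any pair whose estimated ROI displacement exceeds 10 px.

## Synthetic phantoms

`PhantomConfig`/`generate` render a bright quasi-circular vessel on a
uniform background, following a configured trajectory (static, linear
drift, sinusoidal respiration, or single-step jump emulating gross patient
movement), with a logistic contrast-enhancement ramp and optional additive
Gaussian noise.  Defaults emulate the monitor-phase protocol: 0.82
mm/pixel, 3 s interscan, vessel area ≈ 600 mm² (radius 13.8 mm),
enhancement rising from a 45 HU blood baseline to a 250 HU plateau and
crossing the 130 HU trigger mid-series (injection at 3–3.5 ml/s produces a
rise over tens of seconds; exact hemodynamic realism is a non-goal).
Renderer details:

* the disc is drawn by 4×4 supersampled coverage anti-aliasing so
  sub-pixel motion is expressible;
* background tissue defaults to −50 HU (periaortic fat/soft-tissue mix) so
  the vessel is visible before contrast arrives, as a real aorta is;
* an isotropic Gaussian of FWHM 1.6 mm (default) models the in-plane
  reconstruction point-spread of the scanner kernel;
* noise is additive white Gaussian in HU, added after rendering, and is
  the only seed-dependent layer — noise-free renders are bit-identical
  across seeds.

Ground truth (`PhantomTruth`) carries the exact sub-pixel trajectory, the
per-frame half-coverage support masks (standing in for an ideal manual
delineation), and the measured noise-free enhancement curve (mean over the
truth mask).  That measured curve sits slightly below the configured
curve: boundary pixels are partial-coverage, so the deficit is a pure
boundary effect proportional to contrast × perimeter/area — about 1% of
the vessel–background contrast for the hard-edged default geometry (≤ 1 HU
at 100 HU contrast, ~3 HU at 300 HU), larger with the PSF.  Downstream
comparisons therefore use the measured truth curve, not the configured one.

The default fixture suite (fixed seeds, 8 frames each) covers: static;
sub-pixel drift (0.3 px/frame); slow drift (1 px/frame); mild respiration
(AP 1.5 mm / LAT 0.5 mm, period 5 s); moderate respiration (AP 4 mm /
LAT 1.5 mm, period 4 s); an extreme single-step 10 mm excursion; and a
noisy variant (SD 20 HU).  A separate drift phantom (`bolus_demo_config`,
small 5 mm vessel, late contrast onset) is constructed so the vessel fully
exits the static frame-0 ROI before the bolus arrives — the fixed ROI
never triggers while the corrected ROI does.

What the phantoms do **not** model: anatomy (organs, calcified walls,
neighbouring structures), intraluminal texture, streak/beam-hardening
artefacts, 3-D/through-plane motion, scanner physics.  Passing tests on
phantoms therefore validate the geometry, units, statistics and plumbing of
the pipeline — they do not certify flow accuracy on clinical images, where
real texture substantially changes the conditioning of the flow problem
(see below).

## Method-comparison statistics

`MethodComparison(x, y).fit()` computes:

* **Pearson r** with the two-sided *t*-transform p-value (via
  `scipy.stats.pearsonr`);
* **Passing–Bablok regression**: all pairwise slopes
  `S_ij = (y_j − y_i)/(x_j − x_i)` with 0/0 pairs skipped, equal-x pairs
  with differing y counted as signed infinite slopes (+∞ at the top of the
  ranking), slopes exactly −1 excluded, and the slope taken as the median
  shifted upward by `K = #{S_ij < −1}` — the construction that makes the
  estimate invariant under exchange of the methods.  Even counts average
  the two central shifted order statistics.  Confidence bounds use the
  rank-based normal approximation
  `w = z √(n(n−1)(2n+5)/18)`; the intercept is `median(y − b·x)` with its
  CI from the slope bounds.  No cusum linearity test is computed.
* **Bland–Altman**: bias = mean of `d = y − x`, limits of agreement
  `bias ± k·SD(d)` with sample SD (n−1) and k = 1.96 by default.

The pipeline convention is x = delineation-based movement (reference),
y = optical-flow movement (test).

## Known limitations

* **Proportional flow underestimation on homogeneous sections.**  With
  α = 5 and 100 iterations, the smoothness term propagates rim flow roughly
  8 px (the Jacobi diffusion length √(2n/3)) into a gradient-free lumen.
  For the default vessel (radius ≈ 17 px) the ROI-mean therefore recovers
  only ~0.45 of a rigid translation, almost independently of edge
  softness, contrast or step size; recovery reaches ~0.8–0.9 for small
  sections (radius ≲ 8 px) and for gradient-rich objects such as the
  Gaussian-blob validation target (0.93 at a 1 px shift).  Consequently the
  pooled phantom-suite comparison gives high correlation (r ≈ 0.94) but a
  Passing–Bablok slope ≈ 0.43 — a proportional bias intrinsic to
  single-resolution Horn–Schunck on a texture-free lumen at this iteration
  budget, not a property of the statistics or the tracking.
* Displacements of several pixels per pair exceed the linearisation range;
  the single-step 10 mm excursion is quantified but its flow estimate is
  unreliable by construction.
* The solver is 2-D; through-plane motion appears as intensity change and
  corrupts the brightness-constancy assumption, as does the contrast ramp
  itself during steep enhancement.
* Anisotropic in-plane spacing is rejected rather than averaged; image
  stacks store `HU + 1024` in unsigned 16-bit, so HU below −1024 cannot be
  represented in that dialect.
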