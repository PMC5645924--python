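# Methods

## Coordinate transform

The anatomical frame is a per-video-frame rigid pose computed from two
landmarks: the anteroinferior vertices of C2 and C4. In v-flipped image
coordinates $(u, -v)$, the unit $+y$ axis is the normalised C4→C2 vector and
$+x'$ is 90° clockwise from it (image-right); a point $q$ maps to
$(x, y) = s\,(-[R^\top(q'-p')]_1,\; +[R^\top(q'-p')]_2)$, so $+x$ output
points image-left (anterior in a standard lateral projection) and $+y$ runs
up the cervical axis. The transform is implemented as this operational
sequence (v-flip → rigid change of frame → x-negation → scale) rather than as
a single matrix product; the sequence reproduces all the conventions the
frame is defined by (origin at C4, $y$ toward C2, $x$ to image-left) and is
trivially testable: it is an isometry up to $s$, invariant under any common
rigid motion of $\{q, \mathrm{C2}, \mathrm{C4}\}$, and sends C2 to
$(0, s\,\lVert \mathrm{C2}-\mathrm{C4}\rVert)$ exactly.

Calibration uses the **first** $n$ frames (default 3) in which both coin
markers are present — a deterministic selection — and divides the reference
length (default 24.0 mm) by the *mean of per-frame pixel distances*, not the
distance of mean points. One scale factor serves the whole recording;
per-frame recalibration drift is not modelled. Coincident coin marks or a
coincident C2/C4 pair are hard errors, not warnings.

## Data model and file formats

Marker tables are UTF-8 CSV with header `frame,marker,u,v`, 0-based frame
indices, `#` comments, and an optional `# fps=<float>` comment (an explicit
fps argument wins). The marker vocabulary is a closed, case-sensitive set of
14 tokens; structures whose geometry needs two points (coin, epiglottis, UES)
are marker *pairs* (`coin_a/coin_b`, `epiglottis_base/epiglottis_tip`,
`ues_anterior/ues_posterior`). Missing markers are simply absent rows: no
copy-forward of stale positions is ever performed, and downstream series
carry NA at those frames. Event logs are `event,frame` CSV validated against
a 20-name catalogue; the first two names are the swallow onset/offset events
used for the pharyngeal transit time, the rest are editable placeholders
(`event_03`…`event_20`). Coordinates are written with `repr` so round-trips
are exact at full float precision.

## Smoothing

Smoothing acts on anatomical-frame component series (x, y, and derived
angles) *before* differentiation — differentiating the smoothed series is
the only order under which a smoothed velocity plot is consistent with its
displacement plot. NAs are compressed out before fitting and re-inserted
afterwards, so gaps neither bias nor receive estimates.

* **Moving average** (default, span 5): centered mean whose window shrinks
  symmetrically near the edges to the largest odd width that fits, leaving
  the endpoints unchanged. Even spans are rejected rather than silently
  adjusted.
* **Savitzky–Golay**: scipy's filter with `mode="interp"` — the edge
  half-windows take the polynomial fitted on the one-sided terminal window,
  evaluated at the edge samples. Degree must be below the span. With degree 0
  it coincides with the moving average at interior samples.
* **LOWESS family**: at each sample, a tricube-weighted least-squares
  polynomial over the $k$ nearest neighbours in time ($k$ given directly or
  as a fraction of the series length), local degree 1 (lowess) or 2 (loess).
  Robust variants run 5 bisquare re-weighting iterations with scale
  $6\,\mathrm{median}|r|$. Implemented in-package because no installed
  library provides the degree-2 and robust variants under a sample-count
  span; the non-robust linear variant is cross-checked against
  statsmodels' lowess in the tests.
* **Polynomial**: one global least-squares polynomial in time.

All methods are shift- and scale-equivariant and length-preserving; these are
enforced as property tests across every method.

## Kinematics

Velocities use the exact three-stencil finite difference (forward, central,
backward). The stencil is exact for affine series everywhere and for
quadratics at interior samples; the interior error for smooth signals is
bounded by $(\Delta t^2/6)\max|x'''|$, which the test suite verifies on a
sinusoid and which the phantom tests use as the tolerance for velocity
recovery. Interior NA gaps split a series into contiguous runs and the
stencil is applied per run; no interpolation bridges a gap, and
single-sample runs yield no velocity estimate.

Displacement is measured from the first non-NA frame, or from a configured
motion-start event when one is recorded — both conventions are exposed
because the zero point of "maximal displacement" is a genuine free choice;
first-frame is the default. Peaks are greatest-magnitude-with-sign (signed
series) or maxima (magnitude series), earliest frame on ties, NAs skipped.

Epiglottic tilt is the angle of the base→tip direction: unsigned from the
$+y$ axis in $[0°, 180°]$, or signed from the initial orientation in
$(-180°, 180°]$ with **positive = rotation toward posterior** ($-x$), the
direction of epiglottic folding during a swallow. This sign convention is an
artifact choice and is documented rather than derived. The UES parameter is
the maximum anterior–posterior opening distance; the bolus parameter is peak
planar speed $\sqrt{v_x^2 + v_y^2}$ (one number, not per-axis).

## Phantom

The simulator emulates a bench validation instrument: an in-line slider–crank
($d(\theta) = r\cos\theta + \sqrt{l^2 - r^2\sin^2\theta}$, $\theta = \theta_0
+ \omega t$, analytic velocity used as ground truth) driving a hyoid-like
marker along the cervical axis, and a rigid belt–pulley ($\varphi = \varphi_0
+ \rho\,\omega t$) driving the epiglottis tip direction. Default conditions:
$r = 10$ mm, $l = 50$ mm, $\omega = \pi$ rad/s, 30 fps, 2 s, rendered at
4 px/mm — at these values the sampling grid hits both dead centers, so the
analytic peak-to-peak displacement is exactly $2r$. Marking jitter is
i.i.d. isotropic Gaussian pixel noise per marker per frame from a seeded
generator (seed recorded in the output metadata); `c2_c4_drift` applies a
slow sinusoidal *rigid whole-scene* sway that the moving anatomical frame
must cancel, which the tests verify to 1e-6 mm.

The validity-series grid (`config_grid`) spans 16 configurations with strokes
$2r \approx 6.2$–$48.6$ mm and angular sweeps 10°–160°, one second each —
chosen to mirror the amplitude ranges of a bench validation series. What the
phantom does *not* emulate: fluoroscopic image formation, structure-dependent
marking difficulty (noise is homoscedastic), soft-tissue deformation, bolus
flow, or correlated rater bias. Passing phantom tests therefore demonstrates
correctness of the measurement chain, not clinical accuracy on degraded
images.

## Reliability statistics

ICC is computed from the two-way ANOVA mean squares (subjects × raters).
Default model ICC(2,1) — two-way random effects, absolute agreement, single
measures — appropriate for interrater comparisons of continuous kinematic
measures; ICC(3,1) (two-way mixed, consistency) is selectable for intrarater
use. CIs: ICC(3,1) directly from $F = MS_R/MS_E$; ICC(2,1) via the
Satterthwaite-df F approximation. When the estimate is exactly 1 (zero error
variance) the CI degenerates onto the estimate; the implementation clips the
estimate at $1 - 10^{-12}$ inside the df formula to keep it finite. The
category rule (>0.75 excellent; 0.60–0.75 good; 0.40–0.60 moderate; <0.40
poor) leaves its boundaries formally ambiguous between categories; the
implementation closes them as half-open intervals with 0.75 assigned to good
(excellence requires strictly greater) and 0.60/0.40 to the higher category.
CI coverage is verified by simulation: 500 two-way random-effects tables at
$n = 30$, $k = 2$ with known ICC 0.762 must be covered by the 95% CI at
least 90% of the time (observed ≈ 94–97% across seeds).

Bland–Altman uses the fixed 1.96 multiplier and the $n-1$ SD denominator.
Pearson r/p go through scipy with a brute-force covariance oracle in tests.

## Problem sizes and budgets

Tests and the acceptance script run on short recordings (31–61 frames), the
16-configuration validity grid, and 500 ICC replicates — sizes at which every
closed-form comparison is exact to the stated tolerances and the whole suite
completes in a few seconds. The LOWESS family is $O(nk)$ per pass and is
intended for trajectory lengths typical of a single swallow (tens to a few
hundred frames), not for long continuous recordings.

## Known limitations

* 2-D analysis only; no radial-distortion correction of the fluoroscope and
  no 3-D reconstruction.
* No automatic swallow-phase segmentation or span selection; smoothing
  parameters are user choices.
* The reliability module expects complete (balanced) rating tables.
* GUI-style interactive marking, video decoding and animation rendering are
  out of scope; plot-ready tables are exported instead.
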