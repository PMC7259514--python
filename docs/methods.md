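# Methods

`motionews` implements an analysis pipeline for early warning signals
(EWS) of intentional motion onset, together with the synthetic data
generators needed to exercise every stage without access to recordings.
This note documents the models, the numerical choices, and what the
synthetic generators do and do not emulate.

## The fold-transition model

The onset of a reach is modeled as a slow passage through a saddle-node
(fold) bifurcation.  The fast variable `x` — identified with the body
velocity along the reach axis — obeys

    dx/dt = y + x^2 + xi(t)                 (minimal form)
    dx/dt = y + a x^2 - x^3 + gamma xi(t)   (saturating form)
    dy/dt = epsilon

with `y` a slowly drifting control parameter ("decision momentum") and
`xi` uncorrelated noise.  For `y < 0` the fast dynamics relax to the
stable branch `x_s(y)` at rate `lambda(y) = |2 a x_s - 3 x_s^2|`; as
`y -> 0^-` the branch flattens, `lambda -> 0`, and fluctuations around
the branch become slower (rising lag-1 autocorrelation and decay time)
and larger (variance growing as `sigma^2 ~ (t* - t)^(-1/2)` in the
quasi-static regime, against `(t* - t)^(-1)` for pitchfork/Hopf
transitions).  Past `y = 0` no fixed point remains and `x` escapes; the
quadratic coefficient `a` sets the post-transition plateau (held at a
small positive `y`, the saturating flow settles at the cubic root
`4.000625...` for `a = 4`, i.e. at `a` to within 1e-2).

### Integration

The equations are treated as a discrete map at the readout rate:
explicit Euler for the drift plus one additive noise draw `gamma*xi_k`
per readout (no `sqrt(dt)` scaling — the readout step, 10 ms for the
dot stimuli, is part of the model definition, not a discretization of a
continuum SDE).  Stability of the map requires `|1 + dt*lambda| < 1`,
i.e. `lambda < 2/dt`; configurations are chosen inside this bound.  An
overflow guard clamps `|x|` at `10*max(|a|,1)` and records the clamp
time as the escape time.

A consequence worth knowing: near the bifurcation the passage is slow
and the first-order integrator accumulates error, so escape times sit a
few readouts late relative to a dense-step reference integration and
converge to it as `dt` shrinks.  The test suite pins this behavior.

### Dot-stimulus ensembles

The dot stimuli use the saturating form with `a = 4`, `gamma = 0.063`,
10 ms readouts, 1.5 s duration, and a transition time drawn uniformly
in 350–700 ms (realized by starting the slow variable at
`y(0) = -epsilon t*`).  The drift rate `epsilon` is not part of the
stimulus definition and was fixed at 600/s, inside the admissible band
bounded below (~530/s) by requiring the pre-transition lag-1
autocorrelation baseline to start at or below zero — so the 0.1
detector threshold crossing is a genuine rise — and above (~750/s) by
Euler-map stability at the deepest pre-transition branch.

Each trajectory is detrended by subtracting the quasi-static stable
branch `x_s(y(t))` (zero once `y` has crossed) plus a constant offset
making the pre-transition mean zero, then mirrored by a random sign.
Matched step controls replace the fold dynamics by
`x(t) = a H(t - t*) + xi(t)` with the partner fold trajectory's `t*`
and zero-mean uniform noise whose half-width is the fold arm's mean
pre-transition standard deviation times `sqrt(3)` (variance matching).

## Windowed EWS statistics

All three statistics are computed in sliding windows (default lengths
40/48/60 ms, one-sample stride) with the window mean as reference:
lag-1 autocorrelation AR(1); the autocorrelation decay time `tau` (the
first integer lag at which the windowed autocorrelation falls to `1/e`
of its lag-0 value, reported in ms, missing if no lag within the window
qualifies — no interpolation, since the defining arg-min is discrete);
and the unbiased variance.  Window length in samples is
`round(length_ms * rate / 1000)`.  Detectors return the center time of
the first window with AR(1) > 0.1, the first adjacent-window pair with
a decay-time increase above 20%, and the first window with variance
above a unit-bearing threshold (1.5e-4 (cm/s)^2 for motion-capture
velocity; derived from the early-trial variance ceiling for signals
without an absolute calibration — see below).

## Variance-divergence scaling

Per trial, the divergence point T* is the first threshold crossing of
the windowed variance; the curve on T* +/- 100 ms is extracted, curves
are averaged in blocks of 30 trials synchronized on T*, and each
block-averaged curve is fitted with

    log(sigma^2) = -log(b) + n log(t* - t)

on 48-ms sub-windows advanced by 4 ms over the approach side of the
curve (points at or before T*), keeping the fit with the lowest SSE per
point; ensembles are summarized by the median of fitted exponents with
`|n| < 1.5`.  The model is linear in `(-log b, n)` once `t*` is fixed,
so the fit profiles out the linear pair and searches the 1-D SSE
profile over `t*` (log-spaced scan past the segment end, then bounded
local refinement), with `t*` kept beyond the last fitted point so the
log argument stays positive.  Noiseless power-law curves are recovered
to 1e-6 for `n` in {-1, -1/2, -1/4, 0}.

For the dot simulation the variance threshold is set per ensemble to
the maximum windowed variance observed within each trial's first
100 ms, across trials (the early-trial-ceiling rule).  This extreme-
value rule detects the divergence tightly (within ~2 windows of the
true transition) but grows slowly with ensemble size, so the ensemble
size is part of the procedure: the reference measurement uses
replicates of 300 trajectories — the order of a participant's session
— each deriving its own threshold, with fitted exponents pooled across
replicates (10 replicates by default; ~3000 trajectories, a few tens
of seconds on one CPU).  At these settings the pooled median exponent
is -0.50 with a seed-to-seed spread of ~0.06, separating the fold value
cleanly from the -1 of pitchfork/Hopf transitions.  Points whose
windows straddle T* mix post-transition samples into the variance; the
reported exponent emerges from the printed procedure as is, and
restricting fits to strictly pre-divergence windows would instead
recover the shallower quasi-static local slope of the discrete map
(~-0.3 at 10 ms readouts).

## Synthetic motion-capture trials

Each trial emulates a 240 Hz, seven-sensor recording of an attacking
player's reach, with ground-truth event times exact by construction:

* a latent fold process supplies the shared pre-onset velocity
  fluctuations of the six body sensors.  Its slow variable is held
  deep (branch decay 400/s: per-step multiplier -0.67, alternating
  fluctuations like differentiated broadband noise, velocity AR(1)
  baseline ~ -0.6) and steps to a near-critical hold (decay 20/s,
  lag-1 autocorrelation ~0.92, decay time ~45 ms) at the nominal
  warning point — critical slowing appears there while motion has not
  started;
* the reach displacement is a closed-form minimum-jerk profile
  (amplitude 20 cm, duration 0.5 s) placed so its speed crosses the
  0.05 cm/s onset rule exactly at the body-onset truth time; the
  finger carries the same profile delayed by `body_lead_ms` (52 ms
  default), making the truth lead exact, and the defender's finger
  launches it `blocker_lag_ms` after the nominal warning point;
* sensor noise is independent white position noise per coordinate
  (1.2e-5 cm default).  Sampling phase is uniform relative to the
  grid, so the +-half-sample quantization of detected onsets is
  unbiased in onset differences.

The nominal warning point sits `ews_lead_ms` (131 ms default) before
finger onset.  Windowed detection of the decay-time rise lags the
moment the hold begins by a window-filling delay, so the latent
schedule is shifted 26 ms earlier — a constant calibrated once by
Monte-Carlo (12 ensembles of 300 trials) so the intercept of the
density-filtered regression of finger onset on decay-time rise equals
the nominal lead on average (spread ~4 ms between ensembles).  The
calibration is specific to the default generator parameters and the
60 ms reference window; the decay time at the hold (~11 samples)
exceeds a 40 ms window's lag span, which is why 60 ms — the largest of
the study's window set — is the default analysis window for timing
regressions.

What the generator does **not** emulate: empirical body-sway spectra
(none are published); biomechanical coupling between sensors (all six
body sensors share one latent plus independent noise, so first-PC
loadings are equal in expectation rather than merely similar); a
defender decision process (the response channel is scheduled, not
simulated); and a variance divergence in the motion channels — the
near-critical hold has constant variance by design, so the fold
scaling law is measurable only in the dot simulation, where the fold
dynamics genuinely produce it.  Recovery tests on these trials
therefore validate the detector/regression chain against encoded
timing truths, not against real motor data.  Noise magnitudes are
deliberately small so the printed 0.05 cm/s rule applies to raw first
differences; real tracking data would be low-pass filtered first,
which is out of scope.

## Kinematics

The first principal component is computed over the pooled
sensor-coordinate columns (positions, coordinates as variables),
excluding the finger; loadings are reported as squared-loading percent
per coordinate, and the projection sign is fixed toward the reach.
For threshold-based analyses the PC score is rescaled by
`1/sqrt(n_sensors)`, which makes it commensurate with a single
sensor's cm units in the equal-loading regime (where it equals the
center-of-mass motion).  Onset is the first time the Euclidean norm of
the first-difference velocity exceeds 0.05 cm/s, assigned to the later
sample; the defender's response requires the signed target-axis
velocity component to exceed the threshold in the attacker's
direction.

## Association statistics

Per-trial EWS times are regressed on onset times after removing
low-density outliers: a Gaussian-kernel density (Scott bandwidth) is
evaluated at every point and the retained set is the density
super-level set containing the requested fraction of points (0.96,
0.81, 0.60 mirror the study's three contour levels; 0.81 is the
default).  The level is the empirical quantile of point densities, so
retained fractions track the target within sampling error and the mask
is invariant under affine rescaling of either axis.  Ordinary least
squares of onset on EWS time yields the intercept Delta-t (the mean
lead when the slope is near 1); the plain mean difference over the
retained points is reported alongside as a robustness readout.  For
defender analyses, EWS detections earlier than 200 ms from trial start
are treated as false positives and dropped before filtering.

Reaction-time arms are compared with the two-sided Mann-Whitney test
(rank-biserial effect size `1 - 2U/(n1 n2)`, positive when the first
arm is faster), the two-sample Kolmogorov-Smirnov test, and a shift
function of decile differences using the Harrell-Davis estimator (the
simple empirical quantile is available as an alternative).

## End-to-end runs and determinism

`run_experiment1` chains generation, kinematics, EWS, scaling and
association for block-structured motion-capture ensembles;
`run_experiment3` builds matched fold/control dot ensembles, reports
per-arm detection rates — counting a detection as pre-transition only
when its window lies wholly before `t*`, since centered windows
otherwise leak the step half a window backward — and compares
simulated-observer reaction times (first crossing of `|x| > a/2`).
The early-detection advantage of the fold arm shows in the
pre-transition detection rates; the motion-threshold observer, by
contrast, responds to realized motion, which in the fold arm lags the
matched transition time by the slow-passage escape delay, so its
reaction times are *later* on fold trials.  Reproducing the faster
human responses to fold stimuli would require an observer model that
exploits the warning signals, which is beyond this package's scope.  All randomness flows from a
single seed through `numpy.random.SeedSequence` spawning, reports are
JSON with the config hash, and fixed seeds reproduce byte-identical
outputs.

## Known limitations

* The fitted divergence exponent depends on the ensemble size through
  the extreme-value threshold rule (larger ensembles push detection
  closer to the transition and steepen the fit); the replicate
  structure pins the measurand at the session scale.
* The decay-time estimator is coarse (integer lags within short
  windows); near-critical decay times close to the window span produce
  missing values, which the rise detector skips.
* Euler escape times are biased late by a few readouts near the
  bifurcation (first-order slow-passage error).
* The generator's timing calibration (26 ms alignment offset) holds
  for the default parameters and 60 ms windows; changing window
  length, latent noise, or hold depth requires recalibration.
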