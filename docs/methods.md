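# Methods

## The task model

The toolkit models a rapid reaching assessment in which a seated participant
reaches from a reset position near the chest to spherical targets presented
on an invisible arc at arm's length. The arc is modeled as a sector of a
vertical cylinder centred on the headset position recorded at calibration:

* **radius** — the calibrated arm length (Euclidean headset-to-fingertip
  distance, metres);
* **azimuth sector** — 60° total (half-width 30° about straight ahead);
* **vertical extent** — unbounded: a trial ends wherever the fingertip
  crosses the cylinder, at any height.

The origin is fixed for the whole session; head motion is not compensated
(participants are seated with shoulders against the chair back, so residual
head translation is small relative to the ~0.6 m radius).

A trial's outcome is the **angular endpoint error**: the cone angle at the
origin between the direction to the target centre and the direction to the
point where the fingertip first crossed the surface. This folds horizontal
and vertical miss into a single degrees-valued number; signed azimuth and
elevation components are exposed alongside. For errors below 5° the
quadrature relation `total² ≈ azimuth² + elevation²` holds to better
than 1%.

Numerics: the cone angle uses `atan2(|u x v|, u . v)` (and its spherical
haversine equivalent in the simulator's closed-form path), which is accurate
at small separations where a naive `arccos` of the dot product loses half
the available precision. Crossing detection scans consecutive trajectory
samples for the first pair whose cylindrical distances straddle the radius
from below and solves the exact segment–cylinder quadratic, interpolating
the timestamp with the same parameter; the returned point sits on the
surface to machine precision. For straight-line reaches the crossing is
therefore independent of sampling density; for smooth curves at a 72 Hz
frame rate the residual is far below 1 mm.

Target placement follows the protocol's only stated constraint — uniformly
random azimuth along the 60° sector. The vertical placement of targets is
not constrained by the protocol description, so the default policy fixes
elevation at origin height (0°), with an optional uniform jitter range for
users who want vertical spread. Whether the original task randomized
elevation is unknown; at the default the error metric is insensitive to this
choice because endpoint noise, not target position, drives the error.

## Protocols

Two interleaved two-condition protocols are implemented, each with
10 practice trials followed by 200 experimental trials (100 per condition,
balanced and uniformly shuffled):

* **visible_invisible** — on half the trials the rendered hand is invisible
  during the reach, removing visual feedback and isolating proprioception.
* **memory_delay** — the target is flashed for 200 ms and the reach is cued
  by a tone 1200 ms after target onset; in the other half the target stays
  visible. Reach time is clocked from target onset, so the tone delay is
  part of it.

Practice trials are generated, stored and flagged; they never enter
analysis. The 500 ms reset delay and the flash/tone intervals are protocol
metadata: they shape the session timeline but not the simulated outcomes.

## The synthetic reacher

Endpoint noise is specified in surface coordinates (azimuth/elevation bias
and SD, degrees), not Cartesian ones, because the outcome is angular and
the radius varies across participants. A reach endpoint is the target
shifted by independent normal draws on each axis, projected to the surface.
With isotropic per-axis SD σ and no bias, the angular error is Rayleigh
with mean σ·√(π/2) — the identity used for all calibration.

Reach shape follows the minimum-jerk law
`x(τ) = x₀ + (x₁−x₀)(10τ³ − 15τ⁴ + 6τ⁵)` sampled at the 72 Hz tracker
rate. The path aims 5% beyond the surface endpoint so the sampled
trajectory always crosses, and total movement time is scaled so the surface
is reached at the drawn duration. Trajectory shape is not an outcome here;
it exists to exercise crossing detection plausibly (real reaches curve and
decelerate; any smooth monotone path with near-zero endpoint velocities
serves the same purpose).

Reach durations are log-normal (`median · exp(σ·Z)`), with an attention
lapse mechanism: with probability `lapse_rate` (default 0.02) a trial's
duration is multiplied by Uniform(3, 8). Lapses give the >3 SD reach-time
outlier filter realistic work — with 100 trials per condition they produce
roughly two removed trials per participant and condition, matching what a
typical session of this kind shows.

### Cohort presets

`exp1_population()` and `exp2_population()` encode healthy-adult cohorts
calibrated so the population-mean angular errors equal the published group
values for the two protocols (visible 2.24° / invisible 3.80°; standard
2.28° / delayed 3.45°), via the Rayleigh identity. Between-participant
spread of each condition's noise level is back-solved from the published
standard errors of those means (±0.25°/±0.19° at n = 20; ±0.27°/±0.32° at
n = 18). Participant draws use a *symmetrically clipped* normal
(mean ± min(3 SD, distance to the positivity floor)), which keeps the
population mean exact while guaranteeing positive SDs — an ordinary
truncation at zero would bias the cohort mean upward by a few hundredths of
a degree, which matters at the precision the recovery tests check.

A participant's noise levels in the two conditions share a common factor
(weight √ρ, default ρ = 0.5): individual motor precision carries over
between conditions, which is what makes most individuals show the same
condition ordering and is consistent with the reported accuracy–precision
correlations. The memory-delay condition is simulated purely as inflated
endpoint SDs; no mechanistic spatial-memory model is attempted, and an
optional bias hook exists but defaults to zero.

`patient_reacher(1|2)` are single-participant presets emulating reachers
with cerebellar ataxia: error levels calibrated the same way to the
published individual condition means (5.23°/8.94° and 3.49°/7.56°), and
per-condition log-normal duration models matched by moments to the
published reach-time means and SDs (≈1.5–4.3 s, heavy-tailed), with
`lapse_rate` 0.03.

### What the simulator does *not* emulate

* Per-participant systematic bias defaults to zero, so a participant's
  precision is deterministically ≈0.52× their accuracy and the simulated
  accuracy–precision correlation is near 1 rather than the ~0.5–0.7 seen
  in real cohorts. The bias hooks exist; the presets do not use them
  because no published value constrains them.
* No learning, fatigue or drift: error-vs-trial slopes are zero in
  expectation for all presets. Slope tests on simulated healthy cohorts
  therefore exercise the null path (their published counterparts were also
  null results).
* No mid-reach feedback corrections, submovements or tracking dropouts.

Passing recovery tests on this generator therefore demonstrates that the
pipeline measures what the noise model puts in — not that real data are
this clean.

## Outcome measures

Per participant and condition, over valid experimental trials:

* **accuracy** — mean angular error (deg);
* **precision** — sample SD (n−1) of the scalar angular error; a 2D
  dispersion ellipse is deliberately out of scope;
* **reach time** — mean after removing trials more than 3 SD from the
  participant's own mean. The filter is single-pass (mean/SD from the full
  sample) and applies **only** to reach-time analyses; error analyses use
  all valid trials.

The abbreviated-protocol subset (`first_n`, canonically 25) keeps each
condition's first n trials in presentation order before any computation.
Error-vs-trial slopes are OLS fits of error on the 0-based
*within-condition* trial index — the conditions are interleaved, and each
condition's slope is reported separately, so within-condition order is the
natural time axis. (For a patient log analyzed globally the alternative
global-index fit would halve the slope scale; the within-condition
convention is used throughout.)

## Inference

* **Paired group design**: Wilcoxon signed-rank on accuracy, precision and
  reach time (T = sum of positive ranks of second−first; zero differences
  dropped; midranks; tie-corrected variance
  `n(n+1)(2n+1)/24 − Σ(t³−t)/48`; z without continuity correction;
  two-sided normal p) — matching the asymptotic output conventions of the
  mainstream commercial packages used for this kind of analysis. Pearson
  correlation of accuracy vs precision per condition; one-sample t tests of
  per-participant slopes against zero.
* **Individual design**: Mann-Whitney U on trial-level errors and
  outlier-filtered reach times (U for the second group, ties one half,
  tie-corrected variance, no continuity correction; both orientations
  exposed since published z signs for this statistic are not used
  consistently in the field), plus a permutation test of each condition's
  slope: 10,000 reshuffles of the error sequence (sampling without
  replacement preserves the value distribution and destroys temporal
  order), two-sided on |slope| with the add-one correction
  `p = (1 + #{|s*| ≥ |s_obs|}) / (B + 1)`.
* A Shapiro-Wilk gate is computed for every measure and reported as a
  diagnostic only; it does not switch test families (rank tests are always
  used for condition contrasts, t tests for slopes).
* No multiple-testing correction is applied; the report carries the count
  of tests performed so readers can apply their own.

Degenerate inputs are explicit errors, not silent fallbacks: all-zero
paired differences, constant samples fed to Shapiro-Wilk/correlation/t
tests, empty groups. A constant series in the permutation test returns
p = 1 by construction.

## Validation strategy and problem sizes

The test suite validates each layer against an independent route:

* geometry against arccos-dot-product and closed-form intersection oracles
  (10,000 random surface pairs at 1e−9°; curved 72 Hz trajectories within
  1 mm of analytic crossings);
* both rank tests against exhaustive enumeration of all sign assignments /
  group labelings for n ≤ 8, including ties: observed statistic, exact null
  mean and variance (which the tie-corrected formulas must reproduce), 100
  random instances per test plus targeted toy cases;
* the Shapiro-Wilk wrapper against values frozen from R's `shapiro.test`;
* the permutation p against the exact p over all orderings at n = 5, 6 and
  a 500-series uniformity check under exchangeable nulls;
* the full pipeline on 200 simulated cohorts (n = 20, 100 trials per
  condition): grand means recover the calibration targets within 3 SEM,
  the accuracy contrast is significant in ≥99% of cohorts at the
  calibrated effect and in ~5% of 200 null cohorts, and the contrast
  survives restriction to the first 25 trials per condition in ≥95% of
  cohorts. These sizes keep the whole suite under a minute per property
  while leaving Monte-Carlo error well below the tested margins.

`scripts/acceptance.py` re-runs the three study designs end to end at their
native sizes (cohorts of 20 and 18, two patient sessions; 10,000
permutations) and reports the pipeline's headline statistics as JSON.
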