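# Methods

## The model

`P(SBA) = 1 − G_k(t)·F(d)` gives the probability that a skilled birth
attendant is present when a woman's active labour begins.  Delivery
without an SBA requires the joint event that (i) labour onset occurs
before her planned move to the maternity waiting home — probability
`F(d)`, where `F` is the CDF of the onset offset ADD − EDD in days —
and (ii) her latent phase is shorter than her access time `t` —
probability `G_k(t)`, where `G_k` is the parity-specific latent-phase
duration CDF in hours.  Onset date and latent-phase duration are
treated as independent.  `d = +∞` (no MWH stay) makes the onset factor
exactly 1.  Because `G_k` is a CDF, P(SBA) is non-increasing in `t` and
non-decreasing in how early the move happens; these monotonicities are
asserted over the full table grid in the test suite.

Units are fixed by construction and never inferred: onset offsets are
days (negative = before the EDD), latent durations are hours.

## Input distributions

**KDE estimation.**  Given an empirical sample, `F` or `G_k` is
estimated by a Gaussian kernel density estimate with bandwidth
`h = 0.3 × sample SD` by default.  The published description of the
estimation settings gives the bandwidth as the scalar "0.3" without
units; we read it as a multiplicative factor on the sample SD (the
common scalar parameterisation, and an absolute 0.3 days would barely
smooth data with SD 9.21 days), while `bandwidth_mode="absolute"`
provides the other reading.  Kernel mass outside the stated value range
(−30..30 d for onset; 0–30 h nulliparous, 0–16 h multiparous latent) is
clipped and the density renormalised, so the estimated CDF is exactly 0
and 1 at the range ends.  Samples outside the range, singleton samples
and zero-variance samples are rejected rather than silently handled.

**Surrogate mixtures.**  The reference cohorts are published only as
summary statistics.  Each preset therefore carries a two-component
(one for the mean/SD-only cohort) truncated normal mixture calibrated
to those statistics:

| preset | constraints | support |
|---|---|---|
| `khambalia` (onset, n=10,243) | mean −1.48 d, SD 9.21 d, mass 0.66 on [−7, 7] d | [−30, 30] d |
| `mongelli` (onset, n=34,249) | mean −1.79 d, SD 11.3 d | [−30, 30] d |
| `friedman_nulliparous` (latent, n=500) | mean 7.1 h, SD 4.0 h, P95 = 20 h | [0, 30] h |
| `friedman_multiparous` (latent, n=500) | mean 5.3 h, SD 4.1 h, P95 = 14 h | [0, 30] h |

Components are truncated to the support individually, so the mixture
CDF is exactly 0/1 at the support ends.  Calibration is a deterministic
bounded least-squares solve (fixed initialisation list, no randomness);
every constraint is re-verified by quadrature and a relative residual
above 1e-3 raises a `CalibrationError` naming the violated constraint.
All four presets meet their constraints to ≤ 1e-5 relative.

The two-component family has five free parameters against three
constraints.  The leftover freedom is closed as follows:

* interval-mass constraints use an equal-weight *scale mixture at a
  common location* (peaked centre plus heavy tails — the shape implied
  by 66% central mass coexisting with a 9.21-day SD);
* quantile constraints additionally accept optional *shape points* —
  published CDF values, here the no-MWH column of the printed risk
  tables re-expressed as `G_k(t) = 1 − P(SBA)` — fitted in least
  squares with the summary-statistic constraints dominating (weight
  1e3).  The printed tables are the only published information about
  the full shape of the latent-phase distributions, so they are the
  natural tie-breaker; they are soft data, never constraints.

The multiparous surrogate support is [0, 30] h rather than the 0–16 h
smoothing range used for the multiparous KDE: a 16-hour hard cap is an
estimation-range choice, not a physiological bound, and the printed
constraints (P95 = 14 h with SD 4.1 h) admit a far better-shaped
mixture on the wider support.  The 0–16 h range remains the default
KDE fitting range for empirical multiparous samples.

**Known data inconsistencies.**  The published nulliparous latent-phase
statistics (mean 7.1 h, SD 4.0 h, P95 20 h) are mutually inconsistent
with the printed nulliparous table (whose no-MWH column implies a mean
near 9 h): no mixture honouring the statistics can track that column
better than ≈ 0.19.  The multiparous table *is* nearly consistent; the
calibrated multiparous surrogate reproduces its no-MWH and d ≤ −14
columns within 0.032 (asserted at ±0.05 in the acceptance tests).  A
related consequence: a surrogate pair faithful to the printed
statistics crosses the expected parity ordering (`G_mult ≥ G_null`) by
up to ~0.005 around t ≈ 12–14 h, because the nulliparous P95 of 20 h
with SD 4.0 h forces a narrow main mode that plateaus near G = 0.95
before the multiparous CDF reaches it; the ordering property is
asserted with an explicit 0.01 allowance.

## Risk tables and the wheel

The published grid is reproduced: rows [0,1], [1,2], [2,3] then
half-hour intervals up to [12,12.5] (22 rows) × six scenarios (no MWH,
move on the EDD, 1–4 weeks early).  Each interval conservatively
reports its lowest P(SBA), i.e. the value at the interval's upper
bound; intervals are treated as (lower, upper] so adjacent rows share
no evaluation point (immaterial to outputs under the upper-bound rule,
but well defined).  Colour bands follow the half-open convention that
partitions [0, 1]: salmon < 0.90 ≤ light green < 0.95 ≤ dark green.
Display values round half-up to two decimals; CSV/JSON exports carry
full precision and round-trip exactly (use pandas'
`float_precision="round_trip"` when re-reading the CSV).  The
wheel-device export groups the six scenario columns as six concentric
rings keyed by the interval labels of the outer edge.

The recommendation rule scans candidates from least burdensome (no MWH
stay) to most (earliest move) and returns the first meeting the
threshold — matching the published worked example, where a 90% target
for a multipara 10 h 15 min from care selects the move two weeks before
the EDD, not the earliest candidate.  An unmeetable threshold returns
the best candidate flagged `met=False` instead of raising.

## Bootstrap confidence intervals

Both datasets are resampled with replacement at their original sizes,
independently (mirroring the model's independence assumption); the CDFs
are re-estimated with the same KDE settings as the point estimate
(bandwidth 0.3 × the *resample's* SD) and every cell recomputed.  The
95% CI is the 2.5th/97.5th percentile of the replicates
(linear-interpolation convention, fixed for bit-reproducibility under a
seed).  Defaults: at most 2000 iterations, convergence window 100,
tolerance 1e-3 on the running SD — convergence means the running sample
SD of every cell's replicate stream changed by less than the tolerance
over the trailing window; non-convergence is reported via a flag, not
an exception.  2000 replicates stabilise the extreme percentiles to
roughly ±0.01.  Percentile intervals can (rarely) exclude the plug-in
point estimate; table *displays* widen the interval to contain it,
while the raw `CellCI` bounds stay untouched for statistical checks.

**What coverage means here.**  The percentile bootstrap quantifies
sampling error; its estimand is the KDE-population functional (the
smoothed, truncated CDFs), not the unsmoothed truth.  In a 200-
replication study at the published cohort sizes (10,243 onset / 500
latent), the CIs cover the smoothed estimand at 0.93–0.97 across the
cells probed — effectively nominal.  Against the *raw* surrogate truth,
coverage holds (≥ 0.85) wherever smoothing bias is small relative to
sampling noise (the no-MWH column, the d ≤ −14 columns' tails) but
fails at onset-sensitive cells near the EDD (d = 0, −7), where the
0.3 × SD ≈ 2.8-day kernel biases F by up to ≈ 0.02 — several sampling
SEs at n = 10,243.  The same mechanism puts a deterministic floor of
≈ 0.025 under the end-to-end recovery deviation however large the
synthetic cohorts.  Users comparing KDE-based tables against an
external reference should expect that smoothing bias; it is a property
of the published estimation settings, not of the bootstrap.

## Synthetic cohorts

`sample_cohort` draws i.i.d. values from a preset's calibrated mixture
(seeded `numpy` Generator: component choice, then a truncated-normal
draw), so synthetic cohorts reproduce the published summary statistics
within Monte-Carlo error; defaults use the published cohort sizes.
These generators emulate the *published statistics* of the source
cohorts, not their raw data: real onset data are day-binned (the
generator is continuous), real latent-phase durations come from a
specific clinical definition of onset and active phase, and any
covariate structure beyond parity is absent.  Tests passing on
synthetic cohorts therefore validate the estimation and uncertainty
machinery under a known truth — they do not validate the clinical
accuracy of the published inputs themselves.

## Problem sizes and numerics

Acceptance checks use 100,000-draw cohorts for sampling-based
statistics (Monte-Carlo SE ≈ 0.03 d on the onset mean), 200
replications × ≤ 300 bootstrap iterations for the coverage study, and
the full 22 × 6 grid for table properties.  Quantile inversion uses
Brent's method at 1e-9 (`cdf`/`quantile` round-trip verified at 1e-6);
quadrature moments use adaptive Gauss–Kronrod with mass conservation
checked at 1e-9.  Closed-form truncated-normal moments are hand-coded
(φ/Φ identities) for solver speed and are cross-checked in the tests
against `scipy.stats.truncnorm` and against quadrature and Monte-Carlo
estimates.

## Limitations

Beyond the model's stated scope (no onset/latent-phase correlation, no
EDD or access-time uncertainty, parity as the only covariate): the
surrogate mixtures inherit every limitation of the printed statistics,
including their internal inconsistencies documented above; the
nulliparous table published alongside the model cannot be matched by
any statistics-faithful surrogate and deviates by up to ≈ 0.19 in the
no-MWH column; and KDE smoothing bias at the default bandwidth is
material wherever the underlying density is sharply peaked relative to
0.3 × SD.
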