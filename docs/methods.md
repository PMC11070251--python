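# Methods

`moonchorus` turns recognizer scores from scheduled soundscape
recordings into an inference about how moonlight shapes the calling
activity of acoustic insects.  This note documents the models and
procedures, the parameters that matter, the synthetic data the tests
rely on, and the numerical choices made where the design was open.

## Recording schedule

Recorders run on a nightly duty cycle: one window of `window_duration`
seconds (default 600) at the top of every hour from `night_start_hour`
through `night_end_hour` inclusive (defaults 18:00–06:00, i.e. 13
windows per night), for every night inside a site's operation
intervals.  Schedule arithmetic is done in local civil time using a
fixed UTC offset per site; the package does not consult a timezone
database, so daylight-saving transitions are not modelled (the intended
use is tropical sites without DST).  Whether recorders are aligned to
local or UTC hours is configurable; local is the default.

## Detector post-processing

The upstream recognizer scores short overlapped segments (default 0.8 s
long).  Two conventions are implemented:

* **test mode** (0.2 s hop): maximal runs of contiguous above-threshold
  segments are merged into one detection event per run, summarized by
  the *peak* score.  "Contiguous" means intervals that overlap or abut
  (within 1 e-9 s, for hop-grid floating point); a single
  below-threshold segment breaks a run.  Merged events are what human
  reviewers see.
* **field mode** (0.4 s hop): no merging; the response variable is the
  raw number of above-threshold segments per recording window.  A long
  call therefore contributes several detections — the count is a
  calling-activity index, not a call count.

"Above threshold" is strict (`score > 0.95` by default); both the
threshold and strictness are configurable.  Mean-score aggregation over
a run is deliberately not offered: the peak is the conventional
summary, and nothing downstream depends on the choice.

## Evaluation against human annotations

Matching is class-aware and overlap-based, with both thresholds
inclusive:

* precision: a detection is a true positive if it overlaps **≥ 60 %**
  of the duration of at least one annotation (per annotation — a
  detection straddling two calls at 30 % each is a false positive);
* recall: an annotation is recalled if the union of its intersections
  with all detections covers **≥ 50 %** of its duration.

Many-to-one matching is allowed (no bipartite assignment): several
detections may be true positives against one annotation, and recall
already unions detections, so no double counting arises.  This is the
simplest reading consistent with the criteria and is what the
brute-force oracle in the test suite implements independently.

Because a good recognizer finds faint real calls that annotators
missed, the reference set is tiered: *base* (human annotations),
*base + confirmed* (adding reviewer-confirmed detections) and
*base + unable-to-reject* (further adding detections the reviewer could
not resolve).  Added detections enter as annotations at the detection's
extent unless the reviewer redrew the call's bounds (supplied via event
metadata), which is the mechanism by which recall can *decrease* under
augmentation: the redrawn call may be under-covered by the detections.
Rejected detections never enter a tier; unreviewed ones are treated as
rejected with a warning.  Focal species are those with base+confirmed
precision ≥ 0.84, ≥ 20 reference calls and recall ≥ 0.3 (all
inclusive).

## Lunar covariate

For each recording window the package computes, at the window midpoint:

* the lunar **phase angle** *i* and illuminated fraction
  `(1 + cos i)/2`;
* the topocentric **altitude** (horizontal-parallax-corrected, no
  refraction);
* a waxing/waning flag (sign of the sun–moon elongation);
* a dimensionless **relative ground illumination**
  `fraction × (384 400 km / distance)² × sin(alt) × 10^(−0.4 k (X−1))`,
  with airmass `X = 1/sin(alt)` and extinction coefficient
  `k = 0.25 mag/airmass`, zeroed at or below a 0° horizon cutoff.

Positions come from truncated trigonometric series for the lunar and
solar ecliptic coordinates (about 0.3° accuracy in lunar longitude,
valid 1950–2050).  Near syzygy the illuminated fraction is second-order
insensitive to longitude error, so full/new moon fractions are accurate
to better than 0.002 — ample for an ecological covariate.  The model is
relative, not radiometric: no clouds, canopy, twilight or lux
calibration.  The phase-dependent surface-brightness law (opposition
effect) is *not* applied; the covariate is an illumination index, and
the regression only consumes its ordering and scale.  By default the
covariate entering the model is the relative ground illumination
min-max rescaled to [0, 1] across the dataset; the raw fraction or
altitude can be selected instead, and externally computed columns are
passed through verbatim.  "New moon" and "full moon" prediction points
are the covariate extremes 0 and 1.

## Zero-inflated count mixed model

The response is the per-window, per-species detection count.  The
observation model is a mixture of a structural zero (probability π,
intercept-only on the logit scale) and a count family — negative
binomial NB2 (variance μ + μ²/θ) by default, Poisson optionally — with
a log link:

    log μ = β_species + β_moon(species) · moon
            + u_timeblock + u_site + u_species×site + u_species×timeblock

Random intercepts are independent Gaussians, one variance per factor,
no correlation parameters.  "Time block" defaults to calendar
year-month (configurable key function).  The three candidate mean
structures — full interaction, common slope, species only — share the
random-effect structure and are compared by AIC with Akaike weights
`∝ exp(−ΔAIC/2)`.

**Estimation.**  Random effects are integrated by Laplace
approximation.  The fixed effects are profiled into the inner problem:
a damped Newton iteration finds the joint mode of (β, u) (curvature
clipped to be positive semi-definite, line search on the penalized
log-likelihood, ridge fallback if a factorization fails), and the
marginal log-likelihood is the penalized optimum corrected by
−½ log|D| − ½ log|H_uu|, where H_uu is the group-block curvature at the
mode.  The outer problem — inflation intercept, log θ, and per-factor
log standard deviations (bounded, e.g. log σ ∈ [−5, 2]) — is solved by
L-BFGS-B with finite-difference gradients (step 1e-6), warm-starting
the inner mode between evaluations.  Moment-based starting values
(species-mean intercepts, a zero-excess estimate of π, a
method-of-moments θ, σ = 0.3) are used; optional jittered restarts are
available but off by default.  The degrees of freedom count fixed
effects + variance components + the inflation intercept + dispersion;
AIC = 2k − 2 logL exactly.  Non-convergence flags the result rather
than raising.

The profiled-Laplace objective differs from the exact Laplace ML in
that the log-determinant's dependence on β is not re-optimized; on test
problems the discrepancy against `glmmTMB` (which uses exact automatic
differentiation) is ≲ 0.05 log-likelihood units and < 0.01 on
coefficients — negligible at AIC scale.  The no-random-effects limit
reproduces `statsmodels`' zero-inflated NB to 1e-7.

**Predictions.**  Species effects are population-level: random effects
at zero, zero-inflation thinning applied, expected detections per
window `(1 − π) exp(η)` evaluated at the covariate extremes; the
percent change is `100 (new − full)/new` (positive = less calling under
moonlight; undefined when the new-moon prediction is 0).

**Pseudo-R².**  Marginal (fixed-effects) R² in the Nakagawa style:
`var_f / (var_f + Σσ² + σ²_d)` with the lognormal observation variance
`σ²_d = ln(1 + CV²)`, where `CV² = (1/μ̄ + 1/θ)/(1 − π) + π/(1 − π)`
for the zero-inflated NB (drop 1/θ for Poisson).  The per-species scope
restricts records to one species, so var_f reflects moonlight-driven
variation only.

## Synthetic data

The generator produces the study conditions the analysis assumes, at
two levels.

*Counts*: eight species across four tropical sites, ~13 windows per
night over ~3 months (≈5 000 windows), with per-species new-moon rates
spanning 0.5–17.6 expected detections per window and new-to-full
percent changes within ±35 % (log-linear slopes `ln(1 − pct/100)`,
half positive and half negative), structural-zero probability 0.25,
NB dispersion θ = 0.8, and variance components
{time block 0.15, site 0.15, species×site 0.20, species×time 0.20} on
the log scale.  The moonlight covariate is computed from the real
ephemeris for the simulated schedule.  Counts are drawn gamma–Poisson;
a fixed seed yields byte-identical output (one reproducible substream
per species; soundscape simulation uses one per window × species).

*Soundscapes*: true call intervals from a Poisson process (default 6
calls per window, 0.6–1.6 s long); a configurable fraction (default
0.2) is *faint* — real, scored highly by the emulated recognizer, but
absent from the base human annotation set, which is what makes the
tier machinery testable.  Segments overlapping a call by at least half
a segment draw scores from a high Beta; background segments from a low
Beta; a Poisson number of short false-positive runs is injected away
from true calls.  A review emulator confirms detections matching faint
calls, marks a configurable fraction of the rest unable-to-reject, and
rejects the remainder.

What the generator does **not** emulate: serial correlation across
windows and nights, weather and predator covariates, species
interactions, call-rate diel structure within the night, and acoustic
propagation.  Consequently the generator's unexplained variance is
modest, and the fixed-effects pseudo-R² on synthetic data (~0.3–0.5)
is higher than typical field values for this kind of survey (~0.1);
passing tests demonstrate correct recovery of the generating model,
not field realism.

## Problem sizes used by the test suite and acceptance script

The parameter-recovery study runs 50 replicates of ≈5 000 windows × 8
species (≈40 000 records), fitting the full and no-interaction models
per replicate, and requires ≥ 90 % slope-sign recovery for species with
|slope| ≥ 0.2 and ≥ 90 % AIC wins for the interaction model.  The
acceptance script runs one full three-model comparison at the same
size, a five-replicate sign-recovery pass, a 60-window tiered
soundscape evaluation, and the lunar covariate checks; these sizes are
the package's chosen defaults for a reproducible end-to-end
demonstration.

## Known limitations

* The inflation probability is a single intercept; covariate-dependent
  zero inflation is out of scope.
* No correlation between random effects, and no per-species dispersion.
* Standard errors are not reported; inference is by AIC comparison and
  sign/magnitude of recovered effects.
* The ephemeris ignores ΔT (~0.01° effect) and refraction; the horizon
  cutoff is geometric.
* Min-max rescaling of the covariate makes "new/full moon" dataset
  extremes rather than astronomical events; with short recording spans
  this can compress the true dynamic range.
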