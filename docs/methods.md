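# Methods

## Problem and model

Survival data are subject-level pairs (T, δ): a non-negative follow-up
time and an event indicator (δ = 1 event observed, δ = 0 right-censored).
The survival function S(t) = Pr(T > t) is estimated nonparametrically by
the product-limit (Kaplan–Meier) estimator: at each distinct observed
time t_i with d_i events among the n_i subjects still at risk,

    Ŝ(t) = ∏_{t_i ≤ t} (1 − d_i / n_i).

The curve lists censoring-only times as well as event times (with a
factor of 1), because the downstream smoother operates on the full grid
of distinct observed times. Ties between events and censorings at the
same time follow the standard convention that events occur first, so a
subject censored at t still counts in the risk set at t. Independent
censoring is assumed throughout; interval/left censoring, covariates and
variance estimation (Greenwood) are out of scope — the released object is
a point-estimate curve.

### The disclosure problem

Each step of the raw curve corresponds to d_i events at a known time.
When d_i = 1, an adversary holding a previously released curve can
attribute a new drop to the one subject who joined between releases, and
censoring tick marks likewise reveal individual censoring times. The
defence released by this package is a per-site curve that has been (a)
passed through a smoother or an anonymiser, (b) stripped of censoring
markers, and (c) gated behind minimum-count guards. No mechanism removes
disclosure risk entirely; the evaluation harness quantifies what remains.

## LOESS smoothing with AICc span selection

At each grid point x_i the smoother fits a weighted least-squares
polynomial (degree 1 by default, 2 optional) over the q = ⌈span·n⌉
nearest neighbours on the time axis, with tricube weights
w(u) = (1 − |u|³)³ on u = distance / window-radius (w = 0 at the window
boundary). Distances are raw time differences — the predictor is
univariate, so no standardisation is applied. The fit is linear in the
responses, so a hat matrix L exists with fitted = L·y; ν = tr(L) is the
effective number of parameters and σ² = RSS/(n − ν) the residual-variance
estimate stored on the fit.

The span is chosen by minimising the corrected AIC in the
Hurvich–Simonoff–Tsai form for nonparametric smoothers,

    AICc = log(σ̂²_ML) + 1 + 2(ν + 1)/(n − ν − 2),   σ̂²_ML = RSS/n,

which penalises effective model size sharply at the small n these grids
have. σ̂²_ML is floored at 1e-300 before the log so exactly-interpolated
inputs (e.g. perfectly linear data) select cleanly instead of crashing.
Candidates with n − ν − 2 ≤ 0 or rank-deficient windows are skipped.

**Search strategy.** The fitted values depend on the span only through
the window size q, so AICc is piecewise constant in the span with breaks
at q/n. The selector therefore evaluates one candidate per attainable q
in the search interval (default [0.05, 0.95]) — an exact, deterministic
exhaustive minimisation. A golden-section search was rejected because its
unimodality assumption fails on a piecewise-constant objective; a plain
grid mode (`resolution=`) is retained for cross-checking. On a
137-subject staircase the selected span is small (q ≈ 11 of 138): the
staircase is essentially noiseless, so AICc trades only bias against the
penalty and favours narrow windows. The smoothed release consequently
tracks the raw curve closely in level (mean |Δ| ≈ 0.003) while removing
the step structure.

**Smoothing grid.** The input is the (time, surv) pairs at all distinct
observed times, prepended with an anchor at (0, 1) so the smooth starts
from full survival (toggleable via `anchor=False`; the choice is exposed
because either convention is defensible). Output is evaluated at the same
grid. Smoothed values are clipped to [0, 1] but *not* re-monotonised by
default — the smoother's raw output is the released behaviour; a
`monotonise` flag applies the running-minimum projection for users who
need a valid survival function. Between grid points a smoothed release is
evaluated by linear interpolation (it is no longer a staircase); raw
curves remain right-continuous steps.

## Anonymisation mechanisms

**Probabilistic.** Each selected coordinate v becomes
v·(1 + p/100·ε), ε ~ N(0, 1) i.i.d. under a stated seed (x-axis noise
drawn before y-axis noise, so releases are bit-reproducible). Gaussian
noise is the simplest reading of "a percentage of the value"; the
distribution is pluggable. The repair step then restores a valid
staircase: points are stably sorted by time with residual ties broken by
the minimal representable upward offset, survival is replaced by its
running minimum and clipped to [0, 1]. The running minimum is the
cheapest projection preserving right-continuity; it is a design choice,
not a canonical one.

**Deterministic.** Each point of the (time, survival) cloud is replaced
by the centroid of its k nearest neighbours (Euclidean distance in the
raw plane, the point itself included, ties broken by lower input index
for determinism). k = 1 is the identity; k = n collapses the curve onto
its centre of mass — the degenerate limit that makes this mechanism trade
poorly on skewed survival data, where early-event mass pulls all points
toward it. Axes are deliberately not standardised before computing
distances; with day-scale times this makes the time axis dominate, which
is documented rather than hidden.

Differentially private release mechanisms are intentionally absent: they
require privacy-budget accounting by the calling framework, which the
target deployment does not provide.

## Pipeline, guards and federation

`privacy_enhanced_curve` runs guard → KM → mechanism → clip → suppress
censor marks, and records every parameter (selected span, noise spec and
seed, k) in the release metadata. The disclosure guard refuses datasets
with fewer than `min_subjects` subjects (default 10) or `min_events`
events (default 5); both thresholds are conventions in the spirit of
common federated disclosure settings, configurable, with inclusive
boundaries. Guard reports name the rule that fired and never contain data
values. `method="none"` (raw passthrough, for internal comparisons)
additionally requires an explicit `unsafe_raw` flag.

`federated_curves` applies the pipeline independently per site and
returns one curve — or one guard report — per site. There is no pooled
global curve, and a site's output is a pure function of its own data;
the no-leakage property is tested by replacing the other site's data
arbitrarily and requiring bit-identical output.

## Privacy evaluation

*Step identifiability* returns the raw-curve times with exactly one
event — the steps attributable to an individual.

*Raw release-and-join localisation* compares the step-time sets of the
full and reduced curves: the joiner's event time is the step present in
one and absent from the other. (The *earliest pointwise difference*
between the two curves is deliberately not used as the attack: removing a
subject perturbs risk sets at every earlier time, so the curves first
differ at the first event time, not at the joiner's.) With continuous
times this attack succeeds always — the baseline the smoothing must beat.

*Smoothed localisation* uses an inflection detector on the released
polyline: time t[i+1] is flagged when the discrete second difference
d2[i] of the survival values is significant — |d2[i]| above
`sensitivity` × median |d2| (tiny absolute floor, so linear sequences
yield nothing) — and the preceding second difference is sub-threshold or
of opposite sign. The detector is a stated proxy for reading inflection
points off a plotted curve; no canonical definition exists. The default
sensitivity of 2.5 was calibrated so that a typical 137-subject smoothed
release yields a plot-readable handful of inflections (roughly 2–12)
rather than one per grid point (sensitivity 2) or none at all
(sensitivity ≥ 3); the attack is scored successful when the nearest
detected inflection lies within ±2 time units of the joiner's event time,
a declared convention for "matching" a time read off a curve.

`loo_attack_experiment` repeats both attacks over replicated synthetic
cohorts (default 100 replicates of the 137-subject fixture, one random
event subject withheld per replicate, everything seeded). Typical output:
raw success 100/100, smoothed success ≈ 20–25/100 with a median
localisation error of ≈ 11 time units — the quantitative form of the
qualitative claim that a smoothed release does not reveal when the
joiner's event occurred.

`ablation_study` draws a seeded uniform subsample (e.g. 137 → 50),
releases its curve, removes one further random subject and releases
again, reporting both curves and their sup-norm/mean-absolute distance on
the union grid; fully reproducible from the seed.

## Synthetic data

The generator draws latent event times E and censoring times C
independently per subject and records (min(E, C), 1{E ≤ C}) — exactly the
independent-censoring regime the estimator assumes. Weibull event times
with shape < 1 produce the early-event skew typical of survival cohorts
(median < mean). The veteran-like fixture uses n = 137,
E ~ Weibull(shape 0.9, scale 140) and C ~ Uniform(0, 2000), giving
day-scale times and ~7–9% censoring — the size and gross shape of the
classic veteran lung-cancer cohort with entirely synthetic values. What
the fixture does *not* emulate: integer-day ties (its times are
continuous, so every event is a singleton step — the worst case for
disclosure and the cleanest case for the attack experiment), covariate
structure, and group-specific hazards. Passing tests therefore
demonstrate the mechanisms under idealised independent censoring, not
performance on any real cohort; the optional real-data check only
verifies a user-supplied export's subject count.

## Numerical choices and limitations

- Window degeneracy (all window times equal, or a rank-deficient local
  design) raises a dedicated error; span selection skips such candidates.
- Exact tricube boundary convention: the farthest window point gets
  weight zero.
- Problem sizes: oracle suites use 1000 random datasets of n ≤ 20 for the
  product-limit estimator and 20 datasets of n = 10–50 for the smoother;
  the attack experiment uses 100 replicates of n = 137. These sizes make
  the full suite and the acceptance script each run in a couple of
  minutes on one CPU while keeping the Monte-Carlo rates stable to a few
  percentage points.
- The smoothed release is not guaranteed monotone (see `monotonise`), and
  its inflection structure — hence the attack success rate — depends on
  the detector's sensitivity parameter; both are reported, not hidden.
- No formal privacy guarantee is claimed anywhere: the evaluation is
  empirical, and a determined adversary with auxiliary information can do
  better than the implemented attacks.
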