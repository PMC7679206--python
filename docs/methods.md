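# Methods

## Data model and conventions

An *event* is one app entry: user id, module (medication, food, exercise,
bg, cgm), the time the record entered the app (`entry_time`, mandatory)
and the time the behaviour occurred (`event_time`, optional, falling back
to `entry_time`).  Blood-glucose and CGM events carry a value in mg/dL,
which must be positive; rows violating the schema are rejected at read
time with a per-reason count, never coerced.

**Active day.**  A calendar day (single configured timezone, UTC by
default) with at least one entry.  Active days are keyed on `entry_time`
by default — the interaction with the app is what engagement measures —
with `event_time` selectable.  Day indices are 1-based within the
observation window.

**Observation window.**  180 days, anchored by default at the user's
first active day across modules ("initiation"); a consent-date anchor is
selectable.  A user enters the analyzable cohort only if their whole
window fits inside the data extract, which removes right-censoring from
every metric.  Events before the consent date are excluded with a logged
count.  Module-level first use after the window closes does not count as
module use: all metrics are window-scoped.

**Plausibility bounds** for self-reports: age 16–100 years, height
140–220 cm, weight 45–300 kg.  Out-of-range values become absent (the row
is kept); the filter is idempotent because the bounds are closed.

## Engagement metrics

For a sorted active-day set `a_1 < … < a_k` in a window of length L=180:

- `uar_180 = k / L`; `uar_longevity = k / longevity`; `uar_persistence`
  counts only active days inside the persistence span divided by the
  persistence.  The numerators guarantee all three ratios ≤ 1; for the
  longevity variant every active day already lies in `[a_1, a_k]`.
- `longevity = a_k − a_1 + 1` (inclusive, so a single-day user gets 1 and
  the ratio bounds hold; an exclusive reading would make them fail).
- `persistence`: scanning from `a_1`, the first run of **more than** g=28
  consecutive inactive days ends the span at the last active day before
  it; the run between `a_j` and `a_{j+1}` has `a_{j+1} − a_j − 1` inactive
  days, and the trailing run `L − a_k` counts too (a user silent for the
  last 30 days has discontinued).  Without a qualifying run, persistence
  is L.
- `recency` = mean of the raw consecutive differences `a_{j+1} − a_j`
  (absent below 2 active days); `regularity` = their sample standard
  deviation (n−1) divided by the mean (absent below 3 active days).  The
  raw-difference convention for recency/regularity vs the
  inactive-run convention for the gap rule is deliberate and exposed in
  the code rather than hidden: "days between entries" and "concurrent
  inactive days" are different quantities.
- The permissible gap g is either fixed (study value 28) or derived as
  the ceiling of the linearly interpolated 0.9 quantile of per-user mean
  gaps, computed from the pooled "any" rows.

The pooled "any" row deduplicates days across modules: a day is active if
any module has an entry.  The weekly sensitivity variant replaces day
indices by `ceil(day/7)` (window 26 weeks) throughout; the activity delay
stays on the day scale because it is a point-of-engagement quantity, not
a binned one.

Every metric is validated against an independent brute-force
implementation (literal day-by-day scanning) exhaustively over all 2^12
active-day subsets of a 12-day window and on 10,000 random subsets at
L=180.

## Feature derivation

BMI classes follow the WHO cut points with lower-closed boundaries (25.0
is overweight, 30.0 obese); the three obesity classes collapse to one
level for regression and stay separate in descriptives.  Age bins are
decade bins, lower-closed (50 → "50-60").  The recently-diagnosed proxy:
type 1 — earliest insulin start within 180 days before consent; type 2 —
regimen limited to metformin (case-insensitive substring match against a
small synonym list) with the earliest start inside the lookback; a known
type failing the rule is "no", a missing type or registry is "unknown".
The proxy is monotone in the lookback length by construction.

Baseline fasting-glucose control takes the earliest fasting/preprandial-
tagged reading, else the earliest reading between 05:00 and 09:00, and
tests it against 80–130 mg/dL.  CGM time-in-range control is assessed
over the first 14 days from the user's first CGM reading: control means
≥ 70% of readings within 70–180 mg/dL ("exceeded 70%" is implemented as
≥ 0.70, the consensus target's phrasing, configurable), and the verdict
requires ≥ 70% of the expected 5-minute samples — a standard sufficiency
convention, since "sufficient data" needed an operational definition.
Duplicate timestamps are deduplicated, so the verdict is order-invariant.

No feature is ever null: unknown is an ordinary level everywhere, which
keeps the full cohort in every regression.

## Regression

Mean-precision beta GLM with constant precision φ, fitted by maximum
likelihood (statsmodels `BetaModel`; an independent scipy maximisation of
the hand-written log-likelihood serves as a test oracle).  Candidate
links: logit, probit, cloglog, log — the canonical set for means in
(0, 1); selection minimises AIC (`−2ℓ + 2k` with k counting φ), ties go
to the first candidate in order and AIC/BIC disagreement is logged rather
than resolved.  Ratios of exactly 1 are clamped to 0.99; zeros cannot
occur because each module's fit includes only users with ≥ 1 active day
in it (minimum ratio 1/180), and a zero raises as an upstream bug.

Marginal effects are **average** marginal effects: for a factor level,
the sample mean of `μ̂(x, level on) − μ̂(x, reference on)`; for the module
count, the sample-averaged central numerical derivative.  Standard errors
come from the delta method with a numerical Jacobian of the AME vector
against the full parameter vector and the MLE covariance; significance is
flagged at α = 0.10 (a flag, never a filter — exact p-values are always
reported).  AME × 180 gives the active-day equivalent.  Reference levels:
male, age 30-40, normal BMI, type 1 diabetes, not recently diagnosed,
noninsulin, glucose not in control.

In small cohorts the unknown levels of different factors can coincide
exactly (for example, "recent unknown" decomposes into "diagnosis
unknown" plus "insulin unknown" whenever no user is missing both inputs),
making the design rank-deficient.  `build_design` raises by default,
naming the collinear columns; the pipeline drops the latest dependent
column with a log line instead.

Sensitivity refits (gamma GLM with log link; OLS on log y) report
per-term AME sign agreement with the beta fit; they are checks of
direction, not of magnitude.

## Synthetic cohort generator

Per user: consent date uniform over the enrollment period; age from a
truncated normal (mean 50.4, sd 13.5, range 16–94), gender Bernoulli
(57% female), height normal (169.7 ± 10.6 cm), BMI lognormal (median 33,
σ = 0.28) with weight derived, diabetes type categorical (15/70/9/6% for
t1d/t2d/prediabetes/other), and a medication registry consistent with the
type (t1d: insulin ± bolus; t2d: metformin first line with optional
sulfonylurea/insulin/GLP-1; treatment start within the 180-day lookback
with probability 0.30).  Missingness is applied afterwards to the
self-reported fields only, missing-completely-at-random by default:
gender 60%, body measures 63%, age 2%, diabetes type 10%, medication
registry 24% — the self-report gaps typical of consumer-app profiles.

Per module, a day-granular two-state process: uptake Bernoulli, an
exponential activity delay (clipped at `delay_cap`), then daily activity
`expit(logit(base) + Σ effect·x)` while engaged, churn with a constant
per-day hazard, reengagement with a constant per-day probability while
churned.  Day granularity is deliberate: the metrics are day-granular, so
nothing finer is observable.  Emitted events match the latent timeline
exactly (an invariant under test); bg days get 1 + Poisson(0.5) readings
around a per-user fasting level (population 125 ± 25 mg/dL, first-day
first reading tagged fasting with probability 0.6), cgm days a full
288-reading 5-minute trace around a per-user level (155 ± 35 mg/dL).

The `paperlike` preset encodes the qualitative module ordering of real
diabetes-app cohorts — manual modules (medication, food, bg): high
uptake, persistence around two weeks; device modules (exercise, cgm): low
uptake, persistence beyond 100 days — validated by assertion ranges, not
exact values.  What the generator does **not** emulate: realistic
glycemic dynamics or pharmacology (values are distributional
placeholders sufficient to exercise the control classifiers),
covariate-dependent churn, informative missingness (an option exists for
covariate-dependent missingness stress tests but is off by default), or
the consent-to-initiation attrition rate of real funnels (uptake
parameters target per-module use among initiators).  Passing recovery
tests therefore show the estimation chain is correct under the stated
process, not that real cohorts satisfy it.

## Recovery experiments and problem sizes

The validation experiments (`mhengage.validate`) use a single persistent
module with no churn and no delay, so the expected activity ratio equals
the daily activity probability and the implied true AME has a closed
form (expit contrast averaged over the sample; with churn the contrast
is scaled by the mean engaged fraction, which is covariate-independent
by construction).  Sizes, chosen as the package's standard experiment
scales: AME recovery — 50 replicates of 5,000 users, programmed effects
−0.40 and +0.30 on the logit (implied AMEs ≈ −0.079 and +0.061), success
is |error| ≤ 0.01 per term in ≥ 90% of replicates; type-I calibration —
200 replicates of 1,000 users with no effects, empirical rejection rate
of the female AME at α = 0.10 expected in [0.05, 0.17]; link-selection
consistency — 100 replicates of n = 2,000 with a uniform(−3, 3)
covariate, unit slope and φ = 20 under a logit link (a design wide
enough to make logit and probit distinguishable), logit expected to win
by AIC in ≥ 90%.

## Known limitations

- The beta model is a working model for ratios that are really scaled
  binomial counts; with 180 trials the mean model is what matters and
  the recovery experiments confirm calibration, but per-day dependence
  (weekday cycles, streaks) is not modelled.
- The log link frequently fails to converge on clamped ratios near 1
  (fitted means can exceed 1); failures are caught and logged, and
  selection proceeds over the converged candidates.
- `recency`/`regularity` conventions (raw differences) and the gap rule
  (inactive runs) are configurable readings of ambiguous field usage;
  both are documented above rather than asserted as the only reading.
- The monthly-active-user series uses the raw, uncensored log by design
  (it depicts demand over calendar time), so it is not comparable across
  cohorts with different enrollment spans.
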