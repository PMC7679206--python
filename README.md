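# mhengage

Engagement analytics for mobile-health (mHealth) event logs, built around
the kind of data a diabetes self-management app produces: one record per
app entry, tagged with a user, a module (medication, food, exercise, blood
glucose, continuous glucose monitoring) and timestamps, plus sparse
self-reported user profiles.

The package answers two questions a digital-health team asks of such logs:

1. **How intensively do users engage, module by module?**  Six metrics on
   a fixed 180-day observation window, computed on *active days* (days
   with at least one entry):

   - **user activity ratio** `UAR_im = a_im / 180` for user *i* in module
     *m*, where `a_im` counts active days; variants divide by the user's
     *longevity* or *persistence* instead of 180;
   - **activity delay** — days from consent to first active day;
   - **longevity** — inclusive span from first to last active day;
   - **persistence** — days until the first discontinuation, defined as a
     run of more than 28 consecutive inactive days (the threshold is the
     0.9 quantile of per-user mean inter-entry gaps and can be re-derived
     from any cohort); 180 if the user never discontinues;
   - **recency** — mean days between consecutive active days;
   - **regularity** — coefficient of variation of those gaps.

2. **Which patient characteristics go with engagement?**  The activity
   ratio is a proportion in (0, 1), so it is modelled with a beta
   regression: `y ~ Beta(μφ, (1−μ)φ)` with `g(μ) = Xβ`, the link `g`
   chosen per module by AIC among logit, probit, cloglog and log, and
   ratios of exactly 1 clamped to 0.99.  Covariates (gender, age group,
   WHO BMI class, diabetes type, a recently-diagnosed proxy, insulin use,
   baseline glycemic control, number of modules used) always carry an
   explicit `unknown` level, because missing self-reports are the rule in
   app data, not the exception.  Effects are reported as average marginal
   effects (AME) and translated to active-day equivalents (AME × 180).

Dropout survival curves, user×day event matrices and monthly-active-user
series summarise churn; gamma-GLM and log-OLS refits check the sign
robustness of the regression.

Because real app exports of this kind are proprietary, the package ships a
synthetic cohort generator (`mhengage.simulate`) with a day-granular
two-state engagement process (engaged/churned, covariate-dependent daily
activity, reengagement), heavy self-report missingness and glucose
payloads — with full ground truth recorded, so every estimator can be
scored against what was programmed.

## Worked example

```python
from mhengage.cohort import build_cohort
from mhengage.metrics import GapThreshold, metrics_table
from mhengage.simulate import generate, paperlike_config

cfg = paperlike_config(n_users=150, seed=42)
events, profiles, truth = generate(cfg)
members, report = build_cohort(profiles, events, cfg.data_end)
table = metrics_table(events, members, GapThreshold(28))
print(table.groupby("module")[["uar_180", "longevity", "persistence"]].mean().round(2))
```

prints

```
            uar_180  longevity  persistence
module
any            0.25     108.11        46.74
bg             0.17      91.37        34.81
cgm            0.53     143.91       130.27
exercise       0.34     133.48       109.60
food           0.07      37.56        14.02
medication     0.08      49.09        13.24
```

Read this as the manual-vs-automated contrast: manual-entry modules (food,
medication) are taken up often but churn within two weeks (persistence
13–14 days, activity ratio ≈ 0.07), while device-synced modules (cgm,
exercise) are used by fewer people but persist beyond 100 days with
activity ratios of 0.3–0.5.

The `examples/` directory has one short script per capability (simulation
and attrition, metrics, feature derivation, beta regression with AMEs,
dropout curves); each prints its numbers with a note on what they mean.
A thin CLI mirrors the pipeline stages: `mhengage simulate | cohort |
metrics | features | regress | curves | run`.

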