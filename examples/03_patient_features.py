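"""Derive regression covariates with explicit unknown levels.

Every categorical feature keeps missing self-reports as a first-class
"unknown" level instead of dropping users — in sparse mHealth profiles the
unknowns often carry signal of their own.
"""

from mhengage.cohort import build_cohort
from mhengage.features import build_features, descriptives
from mhengage.metrics import GapThreshold, metrics_table
from mhengage.simulate import generate, paperlike_config

cfg = paperlike_config(n_users=150, seed=42)
events, profiles, truth = generate(cfg)
members, _ = build_cohort(profiles, events, cfg.data_end)
metrics = metrics_table(events, members, GapThreshold(28))

features = build_features(profiles, events, metrics, members)
print("feature columns:", [c for c in features.columns][:9], "...")

desc = descriptives(features)
gender = desc[desc["characteristic"] == "gender"]
print("\ngender distribution over known reports:")
print(gender[["level", "n", "pct_of_known", "n_unknown"]].to_string(index=False))

unknown_share = (features["gender"] == "unknown").mean()
print(f"\nshare with unknown gender : {100 * unknown_share:.1f} % "
      "(the generator injects ~60% missingness, as in real app profiles)")
print("modules used per person   :",
      features["n_modules_used"].value_counts().sort_index().to_dict())
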