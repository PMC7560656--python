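"""Generate a two-cohort synthetic dataset and compare its pooled hourly
activity with the analytic expectation of the generator's intensity model."""

import numpy as np

from circadia import analytic_profile, cohort_hourly_counts, default_config, generate_dataset

cfg = default_config(
    n_users={"D": 200, "RS": 400},
    tweets_per_user={"family": "constant", "value": 100},
    seed=1,
)
events, profiles = generate_dataset(cfg)
print(f"generated {len(events)} events for {len(profiles)} users in 2 cohorts")

d_users = set(profiles.loc[profiles.cohort == "D", "user_id"])
_, counts = cohort_hourly_counts(events[events.user_id.isin(d_users)], profiles)
empirical = 100 * counts.sum(axis=0) / counts.sum()
expected = analytic_profile(cfg.intensity["D"])

print("\nhour  expected%  empirical%   (D cohort)")
for h in (3, 4, 5, 12, 21, 22):
    print(f"{h:4d}  {expected[h]:8.2f}  {empirical[h]:9.2f}")
print(
    f"\nmax |empirical - expected| = {np.abs(empirical - expected).max():.2f} pp"
    " — the generated hours follow the configured circadian intensity,"
    " with the D cohort's night suppression (3-5 h) and evening boost (19-23 h)."
)
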