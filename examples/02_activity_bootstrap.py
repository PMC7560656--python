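"""Bootstrap the between-cohort difference in hourly activity levels and
report which hours differ significantly."""

import numpy as np

from circadia import (
    bootstrap_difference,
    cohort_activity_profile,
    cohort_hourly_counts,
    default_config,
    generate_dataset,
    relative_difference,
)

cfg = default_config(
    n_users={"D": 300, "RS": 1200},
    tweets_per_user={"family": "constant", "value": 100},
    seed=4,
)
events, profiles = generate_dataset(cfg)
by_cohort = {}
for cohort in ("D", "RS"):
    users = set(profiles.loc[profiles.cohort == cohort, "user_id"])
    _, by_cohort[cohort] = cohort_hourly_counts(events[events.user_id.isin(users)], profiles)

ratio = relative_difference(
    cohort_activity_profile(by_cohort["D"]), cohort_activity_profile(by_cohort["RS"])
)
diff = bootstrap_difference(by_cohort["D"], by_cohort["RS"], n_replicates=5000, seed=5)

print("hour  D/RS ratio  diff median [95% CI] (pp)  significant")
for h in range(24):
    flag = "*" if diff.significant[h] else ""
    print(
        f"{h:4d}  {ratio[h]:9.3f}  {diff.median[h]:+7.3f} "
        f"[{diff.lower95[h]:+.3f}, {diff.upper95[h]:+.3f}]  {flag}"
    )
sig = np.flatnonzero(diff.significant)
print(
    f"\nhours flagged significant: {sig.tolist()} — an hour is flagged when the"
    " 95% bootstrap CI of the D-RS activity difference excludes 0; the injected"
    " effects sit on hours 3-5 (less active) and 19-23 (more active)."
)
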