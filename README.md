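# circadia

Circadian activity analysis of timestamped social-media event streams for
two-cohort digital-phenotyping studies.

Mental disorders such as depression are strongly associated with disturbances
of the circadian sleep/wake cycle, but it is hard to tell from self-report
whether the disturbance is a *phase shift* (the whole cycle moves) or a
*magnitude change* (activity rises or falls at specific hours). Posting
timestamps on social platforms provide an unobtrusive, longitudinal record of
when people are awake and active. `circadia` implements the full analysis
path for comparing the circadian online-activity pattern of a cohort of users
who self-reported a clinical depression diagnosis (the *D* cohort) against a
creation-date-matched random control cohort (the *RS* cohort) — together with
a synthetic event generator with known ground truth so every statistic can be
validated end to end.

## The statistics at its core

For user *u*, the **activity profile** 𝒜ᵤ is the 24-vector whose entry *h*
is the percentage of *u*'s posts falling in local hour *h* (uniform posting
gives 100/24 ≈ 4.17% everywhere). Cohort profiles 𝒜_D and 𝒜_RS use *pooled
normalization*: hourly counts are summed over users before dividing by the
grand total, so prolific posters weigh proportionally more.

Sampling variability is quantified by **bootstrapping users**: 10,000
replicates each redraw *n* users with replacement and recompute the pooled
profile; per-hour distributions are summarized by median and 95% percentile
CI. The between-cohort difference 𝒜_D − 𝒜_RS is bootstrapped by resampling
both cohorts independently within each replicate; hour *h* differs
significantly at α < 0.05 when its 95% CI excludes 0. The hourly **relative
difference** is the ratio 𝒜_D(h)/𝒜_RS(h). A **phase shift** is tested by
wrapped cross-correlation: Pearson correlation between the two 24-point
series at circular lags −12…+12 h; a maximum at lag 0 means no shift.

Content is compared via **token prevalence**: f_C(t) is the expected number
of occurrences of token *t* per tweet in cohort *C*; a category 𝒞ₓ (e.g.
personal pronouns, rumination, negative affect) pools its tokens, and the
**prevalence ratio** PR(𝒞ₓ) = f_D(𝒞ₓ)/f_RS(𝒞ₓ) measures relative overuse by
the D cohort, overall and per hour (PRʰ, z-scored across hours). Analyses
restrict to tokens appearing in the top-250 list of every hour in both
cohorts, so hourly comparisons are not driven by sporadic tokens.

Supporting steps — cohort filters (retweets, non-English posts, posts
matching the `diagnos*`+`depress*` search pattern, users without a resolvable
timezone), DST-aware localization, largest-remainder creation-month matched
control sampling, and parsing of relative time-of-diagnosis expressions
("2 weeks ago", "recently") into calendar intervals — are all part of the
library.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_phase_shift.py`:

```
lag (h):  -2  -1  +0  +1  +2
corr   : +0.80 +0.94 +0.99 +0.92 +0.75

best lag = 0 h with r = 0.9944
A magnitude change (more evening, less pre-dawn activity) leaves the
correlation maximum at lag 0: the two cohorts share the same phase.

control: a copy shifted by +3 h is detected at best lag = 3 (r = 1.0).
```

The depressed cohort's profile here carries multiplicative hourly effects
(×1.10 on 19–23 h, ×0.73 on 3–5 h) on the shared circadian shape — a pure
magnitude change, which the phase test correctly does not mistake for a
shift. `examples/02_activity_bootstrap.py` then shows the bootstrap flagging
exactly those kinds of hours as significant, e.g.:

```
hour  D/RS ratio  diff median [95% CI] (pp)  significant
   3      0.664   -0.403 [-0.528, -0.273]  *
  22      1.100   +0.495 [+0.211, +0.778]  *
```

— at 3 AM the depressed cohort posts ~34% less, at 10 PM ~10% more, and both
CIs exclude zero.

The full pipeline (ingest → filter → profiles → bootstraps → phase test →
content analysis → tables, figures and a reproducibility manifest) runs from
a JSON config via the library (`circadia.run_pipeline`) or the thin CLI:

```bash
circadia synth --config synth.json --out-dir data/
circadia run --config run.json
```

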