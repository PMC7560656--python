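# Methods

This note records the models, conventions and numerical choices behind
`circadia`, in the order the pipeline applies them.

## Cohort construction and filtering

Events are tweet-like records (id, user, UTC timestamp, text, retweet flag,
language tag); profiles carry each user's timezone, account-creation month
and cohort label. Retained events are English-tagged, are not retweets, do
not match the diagnosis search pattern, and belong to a profiled user with a
resolvable timezone. Rationale: retweet text is not authored by the posting
user; posts matching the `diagnos*` + `depress*` pattern are the sample
selection criterion and would bias content comparisons; and activity must be
binned by local wall-clock hour, which requires a timezone. Each removed
event is counted under the first rule it violates (retweet → non-English →
diagnosis → unknown user → no timezone), so the filter report partitions the
input exactly. Language identification is taken from the record's tag; no
language model is applied.

The diagnosis pattern matches words *beginning* with `diagnos` and `depress`
(word boundary = non-letter→letter transition), deliberately broad:
semantically screening matches ("diagnosing my depressing playlist") is a
human adjudication step outside this package.

The control cohort is drawn so its account-creation-month distribution
matches the reference cohort's, compensating for platform-behavior drift
over time. Month quotas are the largest-remainder apportionment of the
target size across the reference's empirical month distribution (the
rounding rule is a package choice; remainder ties resolve toward earlier
months); within a month, sampling is uniform without replacement. A month
with reference mass but too few candidates is an error listing every
deficient month — quotas are never silently redistributed, since that would
break the matching property the control sample exists for. Matching is at
month resolution, a deliberately coarse and robust choice.

## Timezone localization

IANA zone names resolve through the system zone database and are DST-aware
at the event's instant; fixed offsets (`UTC−05:00`, `+0530`) are also
accepted. The local hour of posting is the only quantity used downstream.

## Time-of-diagnosis intervals

Relative expressions are parsed by a fixed rule grammar: `N unit(s) ago`
(digits or small number words, unit ∈ day/week/month/year), `today`,
`yesterday`, `last week/month/year`, `in YYYY`, `recently`. Positioning
convention: for units longer than a day, "N units ago" denotes the
unit-length span ending the day before `post_date − N·unit` (rolling, not
calendar-aligned — e.g. "2 weeks ago" on 2018-03-15 → 2018-02-22…28);
day-resolution phrases denote the single day `post_date − N`. `in YYYY` is
the calendar year, clamped to the post date; `recently` is the 3 months
ending at the post date. Month/year arithmetic uses calendar offsets with
day-of-month clamping (Mar 31 − 1 month → Feb 28/29). The contraction-free
grammar is rule-based by design — no statistical temporal tagger — and a
JSON phrase→rule table can extend or override it. "I'd" is expanded to
"I would" in tokenization (see below) as a fixed convention even though the
surface form is ambiguous.

Multiple dated statements by one user are combined by interval intersection
(`[max starts, min ends]`, empty → no TOD assigned). Intersection is
commutative, associative and idempotent; parsed intervals never extend past
the statement date.

## Activity profiles and bootstraps

User profiles divide hourly counts by the user's total; cohort profiles use
pooled normalization (sum counts over users, divide by the grand total).
Users with zero retained tweets are excluded before any cohort computation —
they have no defined profile.

Bootstraps resample **users** with replacement, 10,000 replicates by
default, and summarize per-hour distributions by median and percentile
(2.5/97.5) bounds; the percentile method is used because the resampling
distribution of pooled percentages is bounded and can be skewed. The
implementation draws a multinomial resample-weight vector over users per
replicate and pools with a weighted sum — per replicate this is exactly the
pooled profile of a with-replacement resample of n users, computed as one
matrix product (replicates are processed in blocks of 2,000 to bound
memory). One seeded generator drives each bootstrap call, so results are
deterministic given the seed. A replicate whose resample holds zero tweets
in total (possible only when some users have zero counts) is redrawn and
counted, keeping the replicate count fixed and the CI sample size stable.

Difference bootstraps resample the two cohorts *independently* within each
replicate and record the per-hour profile difference in percentage points;
an hour is significant at level α when the percentile CI excludes zero. The
hourly relative difference is the ratio of the two pooled profiles; a zero
denominator at any hour is an error naming the hour.

The phase test computes Pearson correlation between the two 24-point
profiles at every integer circular lag in −12…+12 (the window wraps, never
truncates, so every lag uses the full 24-point overlap). Exact ties in the
maximum resolve to the smallest |lag|, then the negative one; ±12 denote the
same circular shift. Correlation is computed on the raw 24-point series, not
on smoothed curves.

## Content analysis

Tokenization is social-media-aware: URLs, @mentions, #hashtags, emoji,
words with internal apostrophes, numbers, and terminal-punctuation runs each
survive as one token. Then (a) a token whose only capital is its initial
letter is lowercased, except "I"; (b) unambiguous contractions are expanded
from a fixed shipped table (I'm, I'll, I've, I'd, you'll, you've, we're,
they're, can't, won't, don't, didn't, isn't, aren't, wasn't, weren't,
couldn't, shouldn't, wouldn't); ambiguous forms such as "he's" (is/has) pass
through. The tokenizer is idempotent on its own output. Matching is exact
string equality after tokenization; no stemming.

Hour-consistent token selection ranks tokens per local hour by total
occurrence count (ties lexicographic, documented) and intersects the top-k
lists (k = 250 by default) over all 24 hours of both cohorts — per-cohort
ranking, with the union variant available by passing combined corpora.
Prevalence f(t) is occurrences per tweet (counted per instance). Category
prevalence pools token prevalences before dividing (robust to rare tokens);
per-token ratios are reported alongside. Hourly series require at least one
tweet in every hour-stratum of both cohorts; a sparse hour raises an error
naming it rather than propagating NaN, since the hourly series presumes full
coverage — merge hours or enlarge the data upstream. z-scores use the
population standard deviation and are all zeros for a constant series.
Category lexicons are configuration (JSON category→tokens, disjoint unless
overlap is explicitly allowed); emoji are ordinary tokens and belong to
whatever category the lexicon assigns them.

## Synthetic data generator

The generator emulates the study conditions: two cohorts of users, each
posting events whose local hour is drawn categorically from a normalized
24-hour intensity, with per-tweet token emission at cohort-specific rates.

* **Base intensity shape** (both cohorts): a night valley from ~10 PM to
  6 AM with its minimum before dawn, a morning ramp, a first peak at noon,
  an afternoon plateau, the day's highest peak at 9 PM, then a drop. Units
  are arbitrary; only the normalized shape matters.
* **Depressed-cohort effects** (defaults): multiplicative ×1.10 on hours
  19–23 and ×0.73 on hours 3–5, applied before renormalization. These encode
  reported evening-increase/pre-dawn-decrease effect windows of roughly
  +10%/−27%; they are stand-ins chosen for the generator, not a fitted
  model. After renormalization the realized relative differences are ≈ +8%
  and −28%.
* **Per-user totals**: log-normal (median 100, σ_log 0.8 by default) —
  heterogeneous and heavy-tailed like real posting activity; a constant
  family is available for controlled experiments. No empirical distribution
  is claimed.
* **Timestamps**: hour from the intensity, minute/second uniform, date
  uniform over a configurable span (2017–2018 by default), localized from a
  uniformly assigned timezone pool (four US zones + London) and stored in
  UTC, so localization code paths are genuinely exercised. Spring-forward
  gaps are shifted ahead (affects < 0.02% of events, hour 2 only);
  fall-back folds resolve to the DST side.
* **Tokens**: per tweet, each category's occurrence count is Poisson at the
  cohort's rate (optionally modulated by a per-hour multiplier vector),
  tokens uniform within the category, plus background filler tokens at a
  shared rate. The default six categories carry D:RS rate ratios 1.8, 1.7,
  1.45, 1.25, 1.25, 1.35 — magnitudes realistic for depression-related
  lexical comparisons.
* **Determinism**: one `numpy` generator seeded from the config; identical
  (config, seed) pairs give identical output.

What the generator does **not** emulate: real language (texts are bags of
tokens), bursty or autocorrelated posting, weekday/weekend or seasonal
structure, network effects, or user-level heterogeneity in circadian shape
beyond the cohort intensity. Passing tests therefore demonstrate that the
statistics recover known generative structure under the stated conditions —
not that real populations satisfy those conditions.

## Analytic oracle

`analytic_profile` gives the exact expected hourly percentages
100·rate·mult / Σ(rate·mult) of an intensity profile; empirical pooled
fractions of generated data converge to it (verified at ≥10⁵ tweets within
0.5 pp), and injected-effect recovery is judged against it.

## Pipeline, outputs, reproducibility

The pipeline writes per-cohort activity tables, the difference table with
significance flags, the hourly ratio, the phase test JSON, content
prevalence and z-score tables (TSV throughout), figures (activity curves
with periodic cubic-spline interpolation — plotting only, the spline enters
no statistic; difference panels and z-score panels with significant hours
shaded), and a manifest (seed, parameters, package versions, filter report,
cohort sizes) sufficient to reproduce a run bit-exactly. Table reruns with
the same seed are byte-identical; the spline uses a periodic boundary
because the day wraps.

Problem sizes used by the shipped validation runs: the calibration study
uses 100 independent datasets of 200+1,000 users × 50 tweets with
2,000-replicate bootstraps (the percentile CI at the 5% level is adequately
resolved at 2,000 replicates); effect-recovery and the acceptance script use
cohorts of 688/8,791 users × ~100 tweets with the default 10,000 replicates;
content-rate recovery uses 10⁵ tweets per cohort, judged within 3
Monte-Carlo standard errors by the delta method. These sizes are the
package's chosen validation conditions.

## Known limitations

* The diagnosis pattern and TOD grammar cover the documented phrasings only;
  colloquial or indirect time references return no interval.
* Hour-consistency filtering needs dense corpora; small datasets legitimately
  drop sparse category tokens (the pipeline warns and continues, skipping
  categories with no surviving tokens).
* The significance criterion is per-hour; no multiple-comparison correction
  across the 24 hours is applied, matching the analysis convention the
  package implements.
* Content analysis treats tweets as bags of tokens; negation, sarcasm and
  context are invisible to prevalence ratios.
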