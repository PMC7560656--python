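"""Tokenize tweets and compare token-category prevalence between cohorts."""

from circadia import (
    TokenCategory,
    category_prevalence_ratio,
    default_config,
    generate_dataset,
    tokenize,
)

print("tokenizer examples:")
for text in ("I'm Tired", "he's here", "HELLO World \U0001F622", "can't stop #3am"):
    print(f"  {text!r:30s} -> {tokenize(text)}")

cfg = default_config(
    n_users={"D": 300, "RS": 300},
    tweets_per_user={"family": "constant", "value": 100},
    seed=8,
)
events, profiles = generate_dataset(cfg)
cohorts = profiles.set_index("user_id")["cohort"]
labels = events["user_id"].map(cohorts)
tweets_d = list(events.loc[labels == "D", "text"])
tweets_rs = list(events.loc[labels == "RS", "text"])

print(f"\ncategory prevalence ratios ({len(tweets_d)} vs {len(tweets_rs)} tweets):")
model = cfg.token_model
for name, tokens in model.lexicon().items():
    result = category_prevalence_ratio(TokenCategory(name, frozenset(tokens)), tweets_d, tweets_rs)
    truth = model.rates[name]["D"] / model.rates[name]["RS"]
    print(f"  {name:18s} PR = {result.pr:5.2f}  (generator truth {truth:.2f})")
print(
    "\nPR > 1 means the depressed cohort uses the category's tokens more"
    " often per tweet than the random cohort."
)
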