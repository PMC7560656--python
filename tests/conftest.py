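import numpy as np
import pandas as pd
import pytest

from circadia import default_config, generate_dataset


def make_events(hours, user_id="u1", date="2018-06-01", lang="en", is_retweet=False):
    """Events for one UTC-zone user posting once at each given UTC hour."""
    return pd.DataFrame(
        {
            "tweet_id": [f"{user_id}_t{i}" for i in range(len(hours))],
            "user_id": user_id,
            "created_at": pd.to_datetime(
                [f"{date} {h:02d}:30:00" for h in hours], utc=True
            ),
            "text": "hello world",
            "is_retweet": is_retweet,
            "lang": lang,
        }
    )


def make_profiles(user_ids, timezone="UTC", cohort=None):
    return pd.DataFrame(
        {
            "user_id": list(user_ids),
            "timezone": timezone,
            "created_month": "2015-01",
            "cohort": cohort,
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-cohort synthetic dataset shared across tests."""
    cfg = default_config(
        n_users={"D": 25, "RS": 50},
        tweets_per_user={"family": "constant", "value": 60},
        seed=11,
    )
    events, profiles = generate_dataset(cfg)
    return cfg, events, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
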