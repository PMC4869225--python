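from datetime import datetime

import pytest

from agendaset import (
    AccountRecord,
    AccountType,
    SimConfig,
    TweetRecord,
    simulate_accounts,
    simulate_stream,
)

# Published 4x4 contributor-interaction counts (source type x target type),
# used as a desk-scale fixture throughout.
REFERENCE_INTERACTION_COUNTS = {
    (AccountType.INDIVIDUAL, AccountType.INDIVIDUAL): 672,
    (AccountType.INDIVIDUAL, AccountType.ORGANIZATIONAL): 125,
    (AccountType.INDIVIDUAL, AccountType.MEDIA): 267,
    (AccountType.INDIVIDUAL, AccountType.POLICY): 48,
    (AccountType.ORGANIZATIONAL, AccountType.INDIVIDUAL): 132,
    (AccountType.ORGANIZATIONAL, AccountType.ORGANIZATIONAL): 68,
    (AccountType.ORGANIZATIONAL, AccountType.MEDIA): 18,
    (AccountType.ORGANIZATIONAL, AccountType.POLICY): 17,
    (AccountType.MEDIA, AccountType.INDIVIDUAL): 8,
    (AccountType.MEDIA, AccountType.ORGANIZATIONAL): 2,
    (AccountType.MEDIA, AccountType.MEDIA): 9,
    (AccountType.MEDIA, AccountType.POLICY): 1,
    (AccountType.POLICY, AccountType.INDIVIDUAL): 8,
    (AccountType.POLICY, AccountType.ORGANIZATIONAL): 5,
    (AccountType.POLICY, AccountType.MEDIA): 0,
    (AccountType.POLICY, AccountType.POLICY): 2,
}

# Published per-type percentage shares of the three influence measures
# (retweet-impression rank scale, total impressions, amplification).
REFERENCE_SHARE_ROWS = {
    AccountType.INDIVIDUAL: (76.29, 67.79, 96.16),
    AccountType.ORGANIZATIONAL: (11.94, 15.23, 0.02),
    AccountType.MEDIA: (9.34, 11.15, 0.01),
    AccountType.POLICY: (2.43, 5.83, 3.81),
}


def make_tweet(
    tweet_id="t1",
    author_id="a1",
    timestamp=datetime(2014, 1, 5, 12, 0),
    kind="original",
    text="about road accidents",
    matched_keywords=frozenset({"road accidents"}),
    deliveries=100,
    retweet_count=0,
    retweet_impressions=0,
    total_impressions=None,
    retweeted_tweet_id=None,
):
    return TweetRecord(
        tweet_id=tweet_id,
        author_id=author_id,
        timestamp=timestamp,
        kind=kind,
        text=text,
        matched_keywords=matched_keywords,
        deliveries=deliveries,
        retweet_count=retweet_count,
        retweet_impressions=retweet_impressions,
        total_impressions=(
            deliveries + retweet_impressions if total_impressions is None else total_impressions
        ),
        retweeted_tweet_id=retweeted_tweet_id,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_accounts=400,
        days=30,
        base_daily_tweets=15.0,
        shared_spike_days=(4, 11, 18, 25),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_accounts(small_cfg):
    return simulate_accounts(small_cfg)


@pytest.fixture(scope="session")
def small_stream(small_cfg, small_accounts):
    return simulate_stream(small_accounts, small_cfg)


@pytest.fixture
def typed_accounts():
    return [
        AccountRecord("u1", AccountType.INDIVIDUAL, 10),
        AccountRecord("u2", AccountType.ORGANIZATIONAL, 20),
        AccountRecord("u3", AccountType.MEDIA, 30),
        AccountRecord("u4", AccountType.POLICY, 40),
        AccountRecord("u5", AccountType.INDIVIDUAL, 50),
    ]
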