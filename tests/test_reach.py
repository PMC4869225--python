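import random
from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from agendaset import (
    ContributorRecord,
    RetweetEvent,
    amplification_multiplier,
    best_tweet_per_user,
    compute_reach,
    contributor_records,
    drop_zero_retweet,
    filter_above_average_deliveries,
    filter_min_amplification,
    select_regular_tweets,
)
from agendaset.errors import (
    ConfigurationError,
    InconsistentInputError,
    UndefinedMetricError,
    ValidationError,
)

from conftest import make_tweet


def make_event(tweet_id="t1", retweeter="r1", followers=10, ts=datetime(2014, 1, 5)):
    return RetweetEvent(tweet_id, retweeter, followers, ts)


class TestAmplificationMultiplier:
    def test_printed_formula(self):
        assert amplification_multiplier(100, 220) == pytest.approx(2.2)

    def test_no_amplification_identity(self):
        assert amplification_multiplier(50, 50) == 1.0

    @given(st.integers(1, 10**9))
    def test_identity_for_all_x(self, x):
        assert amplification_multiplier(x, x) == 1.0

    def test_event_summation_oracle(self):
        # impressions 200; retweets by followers {30, 70} -> exposure 300
        impressions = 200
        total_exposure = impressions + 30 + 70
        assert amplification_multiplier(impressions, total_exposure) == pytest.approx(1.5)

    def test_zero_impressions_undefined(self):
        with pytest.raises(UndefinedMetricError):
            amplification_multiplier(0, 10)

    def test_exposure_below_impressions_inconsistent(self):
        with pytest.raises(InconsistentInputError):
            amplification_multiplier(10, 5)

    @given(impressions=st.integers(1, 10**6), extra=st.integers(0, 10**6))
    def test_matches_direct_formula(self, impressions, extra):
        total = impressions + extra
        expected = (total - impressions) / impressions + 1.0
        assert amplification_multiplier(impressions, total) == pytest.approx(expected)
        assert amplification_multiplier(impressions, total) >= 1.0


class TestComputeReach:
    def test_no_events(self):
        t = compute_reach(make_tweet(deliveries=10), [])
        assert (t.retweet_count, t.retweet_impressions, t.total_impressions) == (0, 0, 10)

    def test_two_events(self):
        events = [make_event(followers=5), make_event(retweeter="r2", followers=5)]
        t = compute_reach(make_tweet(deliveries=10), events)
        assert (t.retweet_count, t.retweet_impressions, t.total_impressions) == (2, 10, 20)

    def test_mismatched_event_rejected(self):
        with pytest.raises(ValidationError, match="compute_reach"):
            compute_reach(make_tweet(tweet_id="t1"), [make_event(tweet_id="t2")])

    def test_brute_force_summation_oracle(self):
        rng = random.Random(42)
        followers = [rng.randint(0, 5000) for _ in range(50)]
        events = [make_event(retweeter=f"r{i}", followers=f) for i, f in enumerate(followers)]
        t = compute_reach(make_tweet(deliveries=321), events)
        assert t.retweet_count == 50
        assert t.retweet_impressions == sum(followers)
        assert t.total_impressions == 321 + sum(followers)

    @given(st.lists(st.integers(0, 1000), max_size=30))
    def test_additivity(self, followers):
        tweet = make_tweet(deliveries=7)
        events = [make_event(retweeter=f"r{i}", followers=f) for i, f in enumerate(followers)]
        partial = compute_reach(tweet, events[: len(events) // 2])
        full = compute_reach(tweet, events)
        assert full.retweet_impressions >= partial.retweet_impressions
        assert full.total_impressions >= partial.total_impressions
        assert full.total_impressions == full.deliveries + full.retweet_impressions


class TestSelectRegularTweets:
    def test_kind_filter(self):
        tweets = [
            make_tweet(tweet_id="t1", kind="original"),
            make_tweet(tweet_id="t2", kind="reply"),
            make_tweet(tweet_id="t3", kind="retweet", retweeted_tweet_id="t1"),
        ]
        assert [t.tweet_id for t in select_regular_tweets(tweets)] == ["t1"]

    def test_requires_keyword_match(self):
        t = make_tweet(matched_keywords=frozenset())
        assert select_regular_tweets([t]) == []

    def test_generator_ground_truth(self, small_stream):
        kept = select_regular_tweets(small_stream.tweets)
        expected = [
            t for t in small_stream.tweets if t.kind == "original" and t.matched_keywords
        ]
        assert kept == expected

    def test_idempotent(self, small_stream):
        once = select_regular_tweets(small_stream.tweets)
        assert select_regular_tweets(once) == once


class TestDropZeroRetweet:
    def test_counts_0_1_2(self):
        tweets = [
            make_tweet(tweet_id=f"t{c}", retweet_count=c, retweet_impressions=c * 5)
            for c in (0, 1, 2)
        ]
        assert len(drop_zero_retweet(tweets)) == 2

    def test_all_zero(self):
        assert drop_zero_retweet([make_tweet()]) == []

    @given(st.lists(st.integers(0, 5), max_size=40))
    def test_predicate_oracle_and_idempotence(self, counts):
        tweets = [
            make_tweet(tweet_id=f"t{i}", retweet_count=c, retweet_impressions=c)
            for i, c in enumerate(counts)
        ]
        kept = drop_zero_retweet(tweets)
        assert kept == [t for t in tweets if t.retweet_count >= 1]
        assert drop_zero_retweet(kept) == kept


class TestBestTweetPerUser:
    def test_picks_highest_impressions(self):
        tweets = [
            make_tweet(tweet_id="t1", retweet_count=1, retweet_impressions=10),
            make_tweet(tweet_id="t2", retweet_count=1, retweet_impressions=40),
        ]
        assert [t.tweet_id for t in best_tweet_per_user(tweets)] == ["t2"]

    def test_single_tweet_authors_identity(self):
        tweets = [
            make_tweet(tweet_id="t1", author_id="a1"),
            make_tweet(tweet_id="t2", author_id="a2"),
        ]
        assert best_tweet_per_user(tweets) == tweets

    def test_tie_break_earliest_then_id(self):
        base = datetime(2014, 2, 1)
        tweets = [
            make_tweet(tweet_id="tB", author_id="a1", timestamp=base,
                       retweet_count=1, retweet_impressions=5),
            make_tweet(tweet_id="tA", author_id="a1", timestamp=base,
                       retweet_count=1, retweet_impressions=5),
            make_tweet(tweet_id="tC", author_id="a1", timestamp=base + timedelta(hours=1),
                       retweet_count=1, retweet_impressions=5),
        ]
        assert [t.tweet_id for t in best_tweet_per_user(tweets)] == ["tA"]

    def test_brute_force_max_oracle(self):
        rng = random.Random(99)
        tweets = []
        for i in range(200):
            impressions = rng.randint(0, 20)
            tweets.append(
                make_tweet(
                    tweet_id=f"t{i:03d}",
                    author_id=f"a{rng.randint(0, 9)}",
                    timestamp=datetime(2014, 1, 1) + timedelta(hours=rng.randint(0, 500)),
                    retweet_count=1 if impressions else 0,
                    retweet_impressions=impressions,
                )
            )
        result = {t.author_id: t for t in best_tweet_per_user(tweets)}
        for author in {t.author_id for t in tweets}:
            mine = [t for t in tweets if t.author_id == author]
            best = min(mine, key=lambda t: (-t.retweet_impressions, t.timestamp, t.tweet_id))
            assert result[author] == best

    def test_one_tweet_per_author(self, small_stream):
        kept = best_tweet_per_user(small_stream.tweets)
        authors = [t.author_id for t in kept]
        assert len(authors) == len(set(authors))


class TestFilterMinAmplification:
    @staticmethod
    def contributor(cid, multiplier):
        impressions = 100
        total = round(impressions * multiplier)
        return ContributorRecord(cid, 0, impressions, total, (total - impressions) / impressions + 1)

    def test_boundary_kept(self):
        records = [self.contributor(f"c{i}", m) for i, m in enumerate((1.0, 1.2, 1.5))]
        kept = filter_min_amplification(records)
        assert [c.account_id for c in kept] == ["c1", "c2"]

    def test_all_below_empty(self):
        records = [self.contributor("c0", 1.05)]
        assert filter_min_amplification(records) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_min_amplification([], threshold=-1)

    @given(st.lists(st.floats(1.0, 3.0, allow_nan=False), max_size=30))
    def test_predicate_oracle_and_idempotence(self, multipliers):
        records = [self.contributor(f"c{i}", m) for i, m in enumerate(multipliers)]
        kept = filter_min_amplification(records)
        assert kept == [c for c in records if c.amplification_multiplier >= 1.2]
        assert filter_min_amplification(kept) == kept


class TestFilterAboveAverageDeliveries:
    def test_strict_inequality(self):
        rows = [make_tweet(tweet_id=f"t{d}", deliveries=d) for d in (1, 2, 3, 6)]
        kept = filter_above_average_deliveries(rows)
        assert [t.deliveries for t in kept] == [6]

    def test_all_equal_empty(self):
        rows = [make_tweet(tweet_id=f"t{i}", deliveries=5) for i in range(4)]
        assert filter_above_average_deliveries(rows) == []

    def test_empty_input_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert filter_above_average_deliveries([]) == []
        assert "empty" in caplog.text

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=50))
    def test_recomputed_mean_oracle(self, deliveries):
        rows = [make_tweet(tweet_id=f"t{i}", deliveries=d) for i, d in enumerate(deliveries)]
        kept = filter_above_average_deliveries(rows)
        mean = sum(deliveries) / len(deliveries)
        assert kept == [r for r in rows if r.deliveries > mean]


class TestContributorRecords:
    def test_accumulates_per_author(self):
        tweets = [
            make_tweet(tweet_id="t1", author_id="a1", deliveries=100,
                       retweet_count=1, retweet_impressions=120),
            make_tweet(tweet_id="t2", author_id="a1", deliveries=100),
        ]
        (record,) = contributor_records(tweets)
        assert record.impressions == 200
        assert record.total_exposure == 320
        assert record.amplification_multiplier == pytest.approx((320 - 200) / 200 + 1)

    def test_counts_retweets_made(self):
        tweets = [
            make_tweet(tweet_id="t1", author_id="a1"),
            make_tweet(tweet_id="t2", author_id="a2", kind="retweet", retweeted_tweet_id="t1"),
        ]
        by_id = {c.account_id: c for c in contributor_records(tweets)}
        assert by_id["a2"].n_retweets_made == 1
        assert by_id["a1"].n_retweets_made == 0
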