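"""Reach measures and the filter cascades applied to tweet/contributor lists.

Filters are pure functions returning subsets; each is idempotent, and every
filter logs its input size, output size, and the threshold it used so a run's
attrition can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime
from typing import Iterable, Sequence

from .core_io import ContributorRecord, TweetRecord
from .errors import ConfigurationError, InconsistentInputError, UndefinedMetricError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetweetEvent:
    """One retweet of one message, with the retweeter's follower count
    frozen at event time (follower counts are taken "at that time")."""

    original_tweet_id: str
    retweeter_id: str
    retweeter_followers: int
    timestamp: datetime

    def __post_init__(self):
        if self.retweeter_followers < 0:
            raise ValueError("retweeter_followers < 0")


def amplification_multiplier(impressions: int, total_exposure: int) -> float:
    """((total_exposure - impressions) / impressions) + 1.

    Equals 1 exactly when nothing spread beyond direct delivery.
    """
    if impressions == 0:
        raise UndefinedMetricError("amplification multiplier undefined for impressions = 0")
    if total_exposure < impressions:
        raise InconsistentInputError(
            f"total_exposure ({total_exposure}) < impressions ({impressions})"
        )
    return (total_exposure - impressions) / impressions + 1.0


def compute_reach(tweet: TweetRecord, events: Sequence[RetweetEvent]) -> TweetRecord:
    """Fill a tweet's reach counters from its retweet events.

    retweet_count = number of events; retweet_impressions = sum of the
    retweeters' follower counts; total_impressions = deliveries + retweet
    impressions. Reply events, when a caller chooses to include them, are
    accounted identically.
    """
    for e in events:
        if e.original_tweet_id != tweet.tweet_id:
            raise ValidationError(
                f"event for tweet {e.original_tweet_id!r} passed to compute_reach "
                f"of tweet {tweet.tweet_id!r}"
            )
    retweet_impressions = sum(e.retweeter_followers for e in events)
    return replace(
        tweet,
        retweet_count=len(events),
        retweet_impressions=retweet_impressions,
        total_impressions=tweet.deliveries + retweet_impressions,
    )


def select_regular_tweets(tweets: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Keep original (non-retweet, non-reply) tweets that matched a keyword."""
    tweets = list(tweets)
    kept = [t for t in tweets if t.kind == "original" and t.matched_keywords]
    log.info("select_regular_tweets: %d -> %d", len(tweets), len(kept))
    return kept


def drop_zero_retweet(tweets: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Exclude tweets nobody retweeted."""
    tweets = list(tweets)
    kept = [t for t in tweets if t.retweet_count >= 1]
    log.info("drop_zero_retweet: %d -> %d", len(tweets), len(kept))
    return kept


def best_tweet_per_user(tweets: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Keep, per author, the tweet with the highest retweet impressions.

    Ties break deterministically: earliest timestamp, then lexicographic
    tweet_id. Output is ordered by author_id.
    """
    best: dict[str, TweetRecord] = {}
    n = 0
    for t in tweets:
        n += 1
        cur = best.get(t.author_id)
        if cur is None or _best_key(t) > _best_key(cur):
            best[t.author_id] = t
    kept = [best[a] for a in sorted(best)]
    log.info("best_tweet_per_user: %d -> %d", n, len(kept))
    return kept


def _best_key(t: TweetRecord):
    # maximize impressions; among equals prefer earlier timestamp, then
    # lexicographically smaller id (negated orderings via min-style inversion)
    return (t.retweet_impressions, _Neg(t.timestamp), _Neg(t.tweet_id))


class _Neg:
    """Reverses the comparison order of the wrapped value."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __gt__(self, other):
        return self.v < other.v

    def __eq__(self, other):
        return self.v == other.v


def filter_min_amplification(
    contributors: Iterable[ContributorRecord], threshold: float = 1.2
) -> list[ContributorRecord]:
    """Keep contributors whose amplification multiplier is >= threshold.

    The boundary value is kept (a multiplier of exactly the threshold counts
    as "doing quite well").
    """
    if threshold < 0:
        raise ConfigurationError(f"amplification threshold must be >= 0, got {threshold}")
    contributors = list(contributors)
    kept = [c for c in contributors if c.amplification_multiplier >= threshold]
    log.info(
        "filter_min_amplification(threshold=%s): %d -> %d", threshold, len(contributors), len(kept)
    )
    return kept


def filter_above_average_deliveries(rows: Sequence, deliveries=lambda r: r.deliveries) -> list:
    """Keep rows whose deliveries strictly exceed the input's arithmetic mean.

    Works on any row type via the ``deliveries`` accessor (tweets, retweet
    rows, event records). All-equal inputs yield the empty list.
    """
    rows = list(rows)
    if not rows:
        log.warning("filter_above_average_deliveries: empty input")
        return []
    mean = sum(deliveries(r) for r in rows) / len(rows)
    kept = [r for r in rows if deliveries(r) > mean]
    log.info(
        "filter_above_average_deliveries(mean=%.2f): %d -> %d", mean, len(rows), len(kept)
    )
    return kept


def contributor_records(
    tweets: Iterable[TweetRecord], events_by_tweet: dict[str, list[RetweetEvent]] | None = None
) -> list[ContributorRecord]:
    """Accumulate per-account contributor totals from a tweet stream.

    impressions sums the deliveries of everything the account posted;
    total_exposure adds the retweet impressions its messages attracted.
    The amplification multiplier is derived from the two totals.
    """
    events_by_tweet = events_by_tweet or {}
    impressions: dict[str, int] = {}
    exposure: dict[str, int] = {}
    retweets_made: dict[str, int] = {}
    for t in tweets:
        impressions[t.author_id] = impressions.get(t.author_id, 0) + t.deliveries
        rt_impr = t.retweet_impressions or sum(
            e.retweeter_followers for e in events_by_tweet.get(t.tweet_id, ())
        )
        exposure[t.author_id] = exposure.get(t.author_id, 0) + t.deliveries + rt_impr
        if t.kind == "retweet":
            retweets_made[t.author_id] = retweets_made.get(t.author_id, 0) + 1
    out = []
    for account_id in sorted(impressions):
        imp = impressions[account_id]
        tot = exposure[account_id]
        out.append(
            ContributorRecord(
                account_id=account_id,
                n_retweets_made=retweets_made.get(account_id, 0),
                impressions=imp,
                total_exposure=tot,
                amplification_multiplier=(
                    amplification_multiplier(imp, tot) if imp > 0 else 1.0
                ),
            )
        )
    return out
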