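"""Seeded synthetic tweet streams, retweet cascades, coding sheets, and
paired mention trends with exact ground truth.

Every generator derives its random state from ``SimConfig.seed`` alone, so a
fixed config reproduces the identical dataset. Reach counters on generated
tweets are computed from the generated events, which makes them exact — the
analysis pipeline must reproduce them bit for bit.

Follower counts are log-normal (the standard heavy-tailed stand-in), default
median about 200. No follow graph is simulated: retweeters are drawn from
the account pool directly, which suffices for every metric downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from typing import Iterable

import numpy as np

from .classification import CodingSheet
from .core_io import ACCOUNT_TYPES, AccountRecord, AccountType, TweetRecord
from .errors import ConfigurationError
from .reach import RetweetEvent
from .trends import MentionSeries

_DEFAULT_PROPENSITY = {
    "individual": 1.0,
    "organizational": 0.5,
    "media": 0.4,
    "policy": 0.3,
}


@dataclass(frozen=True)
class SimConfig:
    n_accounts: int = 2000
    type_mixture: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05)
    follower_log_mean: float = 5.3  # median exp(5.3) ~ 200 followers
    follower_log_sd: float = 1.2
    days: int = 90
    start_date: date = date(2014, 1, 1)
    base_daily_tweets: float = 40.0
    keyword_rate: float = 0.8
    keywords: tuple[str, ...] = ("traffic accidents", "the traffic accidents", "road accidents")
    # mean retweets attracted per 100 followers, by account type
    retweet_propensity: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROPENSITY)
    )
    reply_rate: float = 0.05
    shared_spike_days: tuple[int, ...] = (5, 12, 19, 26, 33, 40, 47, 54, 61, 68, 75, 82, 87)
    spike_boost: float = 10.0
    newspaper_daily_rate: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if len(self.type_mixture) != len(ACCOUNT_TYPES):
            raise ConfigurationError("type_mixture needs one probability per account type")
        if any(not 0.0 <= p <= 1.0 for p in self.type_mixture):
            raise ConfigurationError("type_mixture probabilities must lie in [0, 1]")
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ConfigurationError(f"type_mixture sums to {sum(self.type_mixture)}, expected 1")
        for name in ("base_daily_tweets", "keyword_rate", "reply_rate", "spike_boost",
                     "newspaper_daily_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(v < 0 for v in self.retweet_propensity.values()):
            raise ConfigurationError("retweet_propensity values must be >= 0")
        if self.days < 0 or self.n_accounts < 0:
            raise ConfigurationError("days and n_accounts must be >= 0")


@dataclass(frozen=True)
class StreamResult:
    """Everything one simulation run produced, plus ground truth."""

    tweets: list[TweetRecord]
    events: dict[str, list[RetweetEvent]]  # original tweet_id -> retweets of it
    daily_activity: list[int]  # all keyword-bearing messages per day

    def events_flat(self) -> list[RetweetEvent]:
        return [e for evs in self.events.values() for e in evs]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent substreams keyed off the single config seed
    return np.random.default_rng([cfg.seed, stream])


def simulate_accounts(cfg: SimConfig) -> list[AccountRecord]:
    """Draw the account pool: types from the mixture, log-normal followers."""
    rng = _rng(cfg, 0)
    type_idx = rng.choice(len(ACCOUNT_TYPES), size=cfg.n_accounts, p=list(cfg.type_mixture))
    followers = np.maximum(
        0, np.rint(rng.lognormal(cfg.follower_log_mean, cfg.follower_log_sd, cfg.n_accounts))
    ).astype(int)
    width = max(6, len(str(max(cfg.n_accounts - 1, 0))))
    return [
        AccountRecord(
            account_id=f"a{i:0{width}d}",
            account_type=ACCOUNT_TYPES[type_idx[i]],
            follower_count=int(followers[i]),
            in_scope=True,
        )
        for i in range(cfg.n_accounts)
    ]


def simulate_stream(accounts: list[AccountRecord], cfg: SimConfig) -> StreamResult:
    """Generate the daily message stream with retweet cascades.

    Per day, Poisson(base_daily_tweets x boost-on-spike-days) messages by
    random authors. Each original attracts Poisson-many retweets with mean
    propensity(author type) x followers / 100; retweeters are sampled from
    the pool and their follower counts frozen into the events. Reach
    counters on returned tweets are exact sums over the generated events.
    """
    rng = _rng(cfg, 1)
    tweets: list[TweetRecord] = []
    events: dict[str, list[RetweetEvent]] = {}
    daily_activity = [0] * cfg.days
    if not accounts or cfg.days == 0:
        return StreamResult(tweets=tweets, events=events, daily_activity=daily_activity)
    followers = np.array([a.follower_count for a in accounts])
    msg_no = 0
    for day in range(cfg.days):
        boost = cfg.spike_boost if day in cfg.shared_spike_days else 1.0
        n_msgs = rng.poisson(cfg.base_daily_tweets * boost)
        day_start = datetime.combine(cfg.start_date + timedelta(days=day), time.min)
        for _ in range(n_msgs):
            author_i = int(rng.integers(len(accounts)))
            author = accounts[author_i]
            has_kw = rng.random() < cfg.keyword_rate
            kw = cfg.keywords[int(rng.integers(len(cfg.keywords)))] if has_kw else None
            kind = "reply" if rng.random() < cfg.reply_rate else "original"
            tid = f"t{msg_no:08d}"
            ts = day_start + timedelta(seconds=msg_no % 86_400)
            msg_no += 1
            text = f"message {tid} about {kw}" if kw else f"message {tid}"
            matched = frozenset([kw]) if kw else frozenset()
            if kw:
                daily_activity[day] += 1

            tweet_events: list[RetweetEvent] = []
            if kind == "original":
                propensity = cfg.retweet_propensity[author.account_type.value]
                lam = propensity * author.follower_count / 100.0
                n_rt = int(rng.poisson(lam)) if lam > 0 else 0
                for r in range(n_rt):
                    rt_i = int(rng.integers(len(accounts)))
                    if rt_i == author_i:  # no self-retweets in the cascade
                        rt_i = (rt_i + 1) % len(accounts)
                    rt_ts = ts + timedelta(seconds=r + 1)
                    tweet_events.append(
                        RetweetEvent(
                            original_tweet_id=tid,
                            retweeter_id=accounts[rt_i].account_id,
                            retweeter_followers=int(followers[rt_i]),
                            timestamp=rt_ts,
                        )
                    )
            rt_impr = sum(e.retweeter_followers for e in tweet_events)
            tweets.append(
                TweetRecord(
                    tweet_id=tid,
                    author_id=author.account_id,
                    timestamp=ts,
                    kind=kind,
                    text=text,
                    matched_keywords=matched,
                    deliveries=author.follower_count,
                    retweet_count=len(tweet_events),
                    retweet_impressions=rt_impr,
                    total_impressions=author.follower_count + rt_impr,
                    retweeted_tweet_id=None,
                )
            )
            if tweet_events:
                events[tid] = tweet_events
            # the retweets themselves are messages in the stream
            for e in tweet_events:
                rt_id = f"t{msg_no:08d}"
                msg_no += 1
                rt_followers = e.retweeter_followers
                tweets.append(
                    TweetRecord(
                        tweet_id=rt_id,
                        author_id=e.retweeter_id,
                        timestamp=e.timestamp,
                        kind="retweet",
                        text=f"RT {text}",
                        matched_keywords=matched,
                        deliveries=rt_followers,
                        retweet_count=0,
                        retweet_impressions=0,
                        total_impressions=rt_followers,
                        retweeted_tweet_id=tid,
                    )
                )
                if kw:
                    daily_activity[day] += 1
    return StreamResult(tweets=tweets, events=events, daily_activity=daily_activity)


def simulate_paired_trends(cfg: SimConfig) -> tuple[MentionSeries, MentionSeries]:
    """Two daily mention series sharing elevated counts on the spike days.

    Both channels draw independent Poisson noise around their base rate;
    on ``shared_spike_days`` the rate is multiplied by ``spike_boost``.
    """
    rng = _rng(cfg, 2)
    dates = tuple(cfg.start_date + timedelta(days=i) for i in range(cfg.days))
    series = []
    for channel, base in (("twitter", cfg.base_daily_tweets), ("newspaper", cfg.newspaper_daily_rate)):
        lam = np.full(cfg.days, base)
        for d in cfg.shared_spike_days:
            if 0 <= d < cfg.days:
                lam[d] *= cfg.spike_boost
        counts = tuple(int(c) for c in rng.poisson(lam))
        series.append(MentionSeries(channel=channel, dates=dates, counts=counts))
    return series[0], series[1]


def truth_coding_sheet(accounts: Iterable[AccountRecord], rater_id: str = "truth") -> CodingSheet:
    """Ground-truth coding sheet straight from the generated account types."""
    return CodingSheet(
        rater_id=rater_id,
        assignments={a.account_id: a.account_type for a in accounts if a.account_type},
    )


def corrupt_coding_sheet(truth: CodingSheet, error_rate: float, seed: int) -> CodingSheet:
    """Independently replace each assignment with a uniformly-chosen
    *different* type with probability ``error_rate``."""
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError(f"error_rate must lie in [0, 1], got {error_rate}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, AccountType] = {}
    for aid in truth.assignments:  # insertion order: deterministic
        current = truth.assignments[aid]
        if rng.random() < error_rate:
            others = [t for t in ACCOUNT_TYPES if t is not current]
            assignments[aid] = others[int(rng.integers(len(others)))]
        else:
            assignments[aid] = current
    return CodingSheet(rater_id=f"{truth.rater_id}-corrupted", assignments=assignments)


def ground_truth_sidecar(cfg: SimConfig, accounts: list[AccountRecord]) -> dict:
    """JSON-serializable ground truth for test assertions."""
    type_counts = {t.value: 0 for t in ACCOUNT_TYPES}
    for a in accounts:
        type_counts[a.account_type.value] += 1
    d = asdict(cfg)
    d["start_date"] = cfg.start_date.isoformat()
    return {
        "config": d,
        "type_counts": type_counts,
        "planted_spike_days": list(cfg.shared_spike_days),
    }


def write_ground_truth(cfg: SimConfig, accounts: list[AccountRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ground_truth_sidecar(cfg, accounts), fh, indent=2)
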