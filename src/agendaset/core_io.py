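"""Domain records and tabular readers/writers shared by every stage.

All files are UTF-8 CSV/TSV with a header row. Records are validated on
construction; a file that round-trips through :func:`write_tweets` /
:func:`read_tweets` reproduces the original record list exactly.

Text matching is literal, case-sensitive substring matching with no Unicode
normalization; callers tracking normalized text should pre-normalize before
ingestion.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

from .errors import ConfigurationError, RowError, SchemaError


class AccountType(enum.Enum):
    """The four account typologies used throughout the pipeline."""

    INDIVIDUAL = "individual"
    ORGANIZATIONAL = "organizational"
    MEDIA = "media"
    POLICY = "policy"

    @classmethod
    def parse(cls, label: str) -> "AccountType":
        try:
            return cls(label.strip().lower())
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise ValueError(f"unknown account type {label!r}; expected one of: {valid}")


ACCOUNT_TYPES: tuple[AccountType, ...] = tuple(AccountType)


@dataclass(frozen=True)
class AccountRecord:
    account_id: str
    account_type: AccountType | None = None  # None == not yet coded / unknown
    follower_count: int = 0
    in_scope: bool = True

    def __post_init__(self):
        if self.follower_count < 0:
            raise ValueError(f"account {self.account_id}: follower_count < 0")


@dataclass(frozen=True)
class TweetRecord:
    """One posted message with its reach counters.

    ``deliveries`` is the author's follower count at post time;
    ``retweet_impressions`` accumulates the followers of every retweeter;
    ``total_impressions`` is deliveries plus retweet impressions (plus reply
    impressions when reply events are supplied).
    """

    tweet_id: str
    author_id: str
    timestamp: datetime
    kind: str  # original | reply | retweet
    text: str = ""
    matched_keywords: frozenset[str] = frozenset()
    deliveries: int = 0
    retweet_count: int = 0
    retweet_impressions: int = 0
    total_impressions: int = 0
    retweeted_tweet_id: str | None = None

    KINDS = ("original", "reply", "retweet")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"tweet {self.tweet_id}: kind must be one of {self.KINDS}")
        for name in ("deliveries", "retweet_count", "retweet_impressions", "total_impressions"):
            if getattr(self, name) < 0:
                raise ValueError(f"tweet {self.tweet_id}: {name} < 0")
        if self.total_impressions < self.deliveries:
            raise ValueError(f"tweet {self.tweet_id}: total_impressions < deliveries")
        if self.retweet_count == 0 and self.retweet_impressions != 0:
            raise ValueError(
                f"tweet {self.tweet_id}: retweet_impressions > 0 with retweet_count = 0"
            )
        if self.kind == "retweet" and not self.retweeted_tweet_id:
            raise ValueError(f"tweet {self.tweet_id}: retweet without retweeted_tweet_id")
        if self.kind != "retweet" and self.retweeted_tweet_id:
            raise ValueError(f"tweet {self.tweet_id}: non-retweet with retweeted_tweet_id")


@dataclass(frozen=True)
class ContributorRecord:
    """Per-account activity totals with the amplification multiplier.

    The multiplier is ((total_exposure - impressions) / impressions) + 1 and
    must be consistent with the two counts whenever impressions > 0.
    """

    account_id: str
    n_retweets_made: int = 0
    impressions: int = 0
    total_exposure: int = 0
    amplification_multiplier: float = 1.0

    def __post_init__(self):
        if min(self.n_retweets_made, self.impressions, self.total_exposure) < 0:
            raise ValueError(f"contributor {self.account_id}: negative count")
        if self.impressions > 0:
            expected = (self.total_exposure - self.impressions) / self.impressions + 1.0
            if abs(self.amplification_multiplier - expected) > 1e-9:
                raise ValueError(
                    f"contributor {self.account_id}: amplification_multiplier "
                    f"{self.amplification_multiplier!r} inconsistent with counts "
                    f"(expected {expected!r})"
                )


@dataclass(frozen=True)
class KeywordSet:
    keywords: tuple[str, ...]

    def __init__(self, keywords: Iterable[str]):
        kws = tuple(keywords)
        if not kws:
            raise ConfigurationError("KeywordSet must contain at least one keyword")
        object.__setattr__(self, "keywords", kws)


def match_keywords(text: str, keywords: KeywordSet) -> frozenset[str]:
    """Return the subset of keywords appearing verbatim in ``text``.

    Matching is exact substring, case-sensitive. Adding keywords to the set
    can only add matches (monotone).
    """
    return frozenset(k for k in keywords.keywords if k in text)


# ---------------------------------------------------------------------------
# CSV plumbing

TWEET_COLUMNS = (
    "tweet_id",
    "author_id",
    "timestamp",
    "kind",
    "text",
    "matched_keywords",
    "deliveries",
    "retweet_count",
    "retweet_impressions",
    "total_impressions",
    "retweeted_tweet_id",
)
ACCOUNT_COLUMNS = ("account_id", "account_type", "follower_count", "in_scope")
CONTRIBUTOR_COLUMNS = (
    "account_id",
    "n_retweets_made",
    "impressions",
    "total_exposure",
    "amplification_multiplier",
)

_KEYWORD_SEP = "|"


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _require_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(header)}")


def _int_field(raw: str, name: str) -> int:
    value = int(raw)  # ValueError on malformed input
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def read_tweets(path, schema: dict[str, str] | None = None) -> list[TweetRecord]:
    """Read tweet records, validating every row.

    ``schema`` optionally maps canonical column names to the names used in
    the file. Rows failing validation are collected and reported together in
    a :class:`RowError` carrying 1-based line numbers.
    """
    schema = schema or {}
    col = {name: schema.get(name, name) for name in TWEET_COLUMNS}
    records: list[TweetRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        _require_columns(reader.fieldnames or [], list(col.values()), path)
        for lineno, row in enumerate(reader, start=2):
            try:
                kws = row[col["matched_keywords"]]
                records.append(
                    TweetRecord(
                        tweet_id=row[col["tweet_id"]],
                        author_id=row[col["author_id"]],
                        timestamp=datetime.fromisoformat(row[col["timestamp"]]),
                        kind=row[col["kind"]],
                        text=row[col["text"]],
                        matched_keywords=frozenset(kws.split(_KEYWORD_SEP)) if kws else frozenset(),
                        deliveries=_int_field(row[col["deliveries"]], "deliveries"),
                        retweet_count=_int_field(row[col["retweet_count"]], "retweet_count"),
                        retweet_impressions=_int_field(
                            row[col["retweet_impressions"]], "retweet_impressions"
                        ),
                        total_impressions=_int_field(
                            row[col["total_impressions"]], "total_impressions"
                        ),
                        retweeted_tweet_id=row[col["retweeted_tweet_id"]] or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                problems.append((lineno, str(exc)))
    if problems:
        raise RowError(problems)
    return records


def write_tweets(records: Iterable[TweetRecord], path) -> None:
    """Write tweet records in the canonical column order (lossless)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(TWEET_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.tweet_id,
                    r.author_id,
                    r.timestamp.isoformat(),
                    r.kind,
                    r.text,
                    _KEYWORD_SEP.join(sorted(r.matched_keywords)),
                    r.deliveries,
                    r.retweet_count,
                    r.retweet_impressions,
                    r.total_impressions,
                    r.retweeted_tweet_id or "",
                ]
            )


def read_accounts(path) -> list[AccountRecord]:
    records: list[AccountRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        _require_columns(reader.fieldnames or [], ACCOUNT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                raw_type = row["account_type"].strip()
                records.append(
                    AccountRecord(
                        account_id=row["account_id"],
                        account_type=AccountType.parse(raw_type) if raw_type else None,
                        follower_count=_int_field(row["follower_count"], "follower_count"),
                        in_scope=row["in_scope"].strip().lower() in ("1", "true", "yes"),
                    )
                )
            except (ValueError, KeyError) as exc:
                problems.append((lineno, str(exc)))
    if problems:
        raise RowError(problems)
    return records


def write_accounts(records: Iterable[AccountRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(ACCOUNT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.account_id,
                    r.account_type.value if r.account_type else "",
                    r.follower_count,
                    "true" if r.in_scope else "false",
                ]
            )


def read_contributors(path) -> list[ContributorRecord]:
    records: list[ContributorRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        _require_columns(reader.fieldnames or [], CONTRIBUTOR_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ContributorRecord(
                        account_id=row["account_id"],
                        n_retweets_made=_int_field(row["n_retweets_made"], "n_retweets_made"),
                        impressions=_int_field(row["impressions"], "impressions"),
                        total_exposure=_int_field(row["total_exposure"], "total_exposure"),
                        amplification_multiplier=float(row["amplification_multiplier"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                problems.append((lineno, str(exc)))
    if problems:
        raise RowError(problems)
    return records


def write_contributors(records: Iterable[ContributorRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(CONTRIBUTOR_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.account_id,
                    r.n_retweets_made,
                    r.impressions,
                    r.total_exposure,
                    # full repr so the written ratio round-trips exactly
                    repr(r.amplification_multiplier),
                ]
            )
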