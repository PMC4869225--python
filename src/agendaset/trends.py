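"""Daily keyword-mention series: construction, max-normalization, spike
detection, and cross-channel spike matching.

The original comparison of channel trends was visual; here it is replaced by
an explicit deterministic procedure — local maxima above a normalized height
threshold, separated by a minimum number of days, greedily matched one-to-one
across channels within a day window. All three parameters are surfaced.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MentionSeries:
    """Gap-free daily mention counts for one channel, with optional
    max-normalized values in [0, 1]."""

    channel: str
    dates: tuple[date, ...]
    counts: tuple[int, ...]
    normalized: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.dates) != len(self.counts):
            raise ValidationError("dates and counts differ in length")
        for d1, d2 in zip(self.dates, self.dates[1:]):
            if (d2 - d1).days != 1:
                raise ValidationError(f"dates must be consecutive days; gap at {d1} -> {d2}")
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be non-negative")
        if self.normalized is not None and len(self.normalized) != len(self.counts):
            raise ValidationError("normalized length mismatch")

    @classmethod
    def from_daily_csv(cls, path, channel: str | None = None) -> "MentionSeries":
        """Read a pre-counted per-day CSV with columns (date, count)."""
        dates, counts = [], []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                dates.append(date.fromisoformat(row["date"]))
                counts.append(int(row["count"]))
        return cls(channel=channel or str(path), dates=tuple(dates), counts=tuple(counts))

    def to_daily_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            header = ["date", "count"] + (["normalized"] if self.normalized else [])
            writer.writerow(header)
            for i, (d, c) in enumerate(zip(self.dates, self.counts)):
                row = [d.isoformat(), c]
                if self.normalized:
                    row.append(repr(self.normalized[i]))
                writer.writerow(row)


@dataclass(frozen=True)
class SpikeMatchReport:
    spikes_a: tuple[int, ...]
    spikes_b: tuple[int, ...]
    matches: tuple[tuple[int, int], ...]
    window_days: int

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def daily_mention_counts(
    items: Iterable, window: tuple[date, date], when=lambda x: x, channel: str = ""
) -> MentionSeries:
    """Count keyword-bearing items per calendar day over a closed window.

    ``when`` extracts a date or datetime from each item. Items outside the
    window are excluded (logged); days with no items count 0.
    """
    start, end = window
    if end < start:
        raise ConfigurationError(f"empty window: {start} .. {end}")
    n_days = (end - start).days + 1
    counts = [0] * n_days
    dropped = 0
    for item in items:
        ts = when(item)
        d = ts.date() if isinstance(ts, datetime) else ts
        if start <= d <= end:
            counts[(d - start).days] += 1
        else:
            dropped += 1
    if dropped:
        log.info("daily_mention_counts: excluded %d item(s) outside %s..%s", dropped, start, end)
    dates = tuple(start + timedelta(days=i) for i in range(n_days))
    return MentionSeries(channel=channel, dates=dates, counts=tuple(counts))


def normalize_series(s: MentionSeries) -> MentionSeries:
    """Divide every count by the series maximum (all-zero stays all-zero)."""
    peak = max(s.counts) if s.counts else 0
    if peak == 0:
        log.warning("normalize_series(%s): all-zero series", s.channel)
        normalized = tuple(0.0 for _ in s.counts)
    else:
        normalized = tuple(c / peak for c in s.counts)
    return MentionSeries(channel=s.channel, dates=s.dates, counts=s.counts, normalized=normalized)


def detect_spikes(
    s: MentionSeries, height: float = 0.3, min_separation: int = 2
) -> list[int]:
    """Indices of local maxima with normalized value >= height.

    A point qualifies when it is >= both neighbours and strictly above at
    least one of them (boundary points compare only their one neighbour), so
    flat series yield no spikes. Detections closer than ``min_separation``
    days keep the taller; ties keep the earlier.
    """
    if not (0.0 < height <= 1.0):
        raise ConfigurationError(f"spike height must lie in (0, 1], got {height}")
    if s.normalized is None:
        raise ValidationError("detect_spikes requires a normalized series")
    v = np.asarray(s.normalized)
    if len(v) == 0 or v.max() == 0:
        return []
    candidates = [
        i
        for i in range(len(v))
        if v[i] >= height
        and (i == 0 or v[i] >= v[i - 1])
        and (i == len(v) - 1 or v[i] >= v[i + 1])
        and ((i > 0 and v[i] > v[i - 1]) or (i < len(v) - 1 and v[i] > v[i + 1]))
    ]
    # enforce separation, preferring taller spikes (earlier on ties)
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: (-v[i], i)):
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    return sorted(kept)


def match_spikes(a: Sequence[int], b: Sequence[int], window_days: int = 1) -> SpikeMatchReport:
    """Greedy one-to-one nearest-day matching of two spike index lists.

    Candidate pairs within ``window_days`` are taken closest-first (ties by
    earlier day); each spike participates in at most one match.
    """
    if window_days < 0:
        raise ConfigurationError(f"window_days must be >= 0, got {window_days}")
    if list(a) != sorted(a) or list(b) != sorted(b):
        raise ValidationError("spike index lists must be sorted")
    pairs = sorted(
        ((ia, ib) for ia in a for ib in b if abs(ia - ib) <= window_days),
        key=lambda p: (abs(p[0] - p[1]), p[0], p[1]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for ia, ib in pairs:
        if ia not in used_a and ib not in used_b:
            matches.append((ia, ib))
            used_a.add(ia)
            used_b.add(ib)
    return SpikeMatchReport(
        spikes_a=tuple(a), spikes_b=tuple(b), matches=tuple(sorted(matches)), window_days=window_days
    )
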