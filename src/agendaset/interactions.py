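"""Source -> target retweet-interaction matrix by account type.

Rows are the source of influence (the author whose message was retweeted),
columns the target (the account that retweeted). Cells count unique
(source, retweeter) user pairs by default; a switch allows raw-event
counting. Self-retweets are never counted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from ._util import round_half_up
from .core_io import ACCOUNT_TYPES, AccountRecord, AccountType
from .errors import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class InteractionEvent:
    source_author_id: str  # creator of the retweeted message
    retweeter_id: str
    deliveries: int = 0

    def __post_init__(self):
        if self.deliveries < 0:
            raise ValueError("deliveries < 0")


@dataclass(frozen=True)
class InteractionMatrix:
    counts: dict[tuple[AccountType, AccountType], int]  # (source, target) -> n
    row_totals: dict[AccountType, int]
    col_totals: dict[AccountType, int]
    grand_total: int

    def __post_init__(self):
        cells = sum(self.counts.values())
        if not (cells == sum(self.row_totals.values()) == sum(self.col_totals.values()) == self.grand_total):
            raise ValidationError("interaction matrix totals are inconsistent")

    @classmethod
    def from_counts(cls, counts: Mapping[tuple[AccountType, AccountType], int]) -> "InteractionMatrix":
        full = {(s, t): int(counts.get((s, t), 0)) for s in ACCOUNT_TYPES for t in ACCOUNT_TYPES}
        row = {s: sum(full[(s, t)] for t in ACCOUNT_TYPES) for s in ACCOUNT_TYPES}
        col = {t: sum(full[(s, t)] for s in ACCOUNT_TYPES) for t in ACCOUNT_TYPES}
        return cls(counts=full, row_totals=row, col_totals=col, grand_total=sum(full.values()))


def build_interaction_matrix(
    events: Iterable[InteractionEvent],
    accounts: Iterable[AccountRecord],
    unique_pairs: bool = True,
) -> InteractionMatrix:
    """Aggregate retweet interactions into the 4x4 type-by-type matrix.

    Every referenced account must carry a coded type. With
    ``unique_pairs=True`` (default) duplicate (source, retweeter) pairs are
    counted once — the matrix counts interacting users, not raw retweets.
    """
    types = {a.account_id: a.account_type for a in accounts}
    pairs = []
    untyped: set[str] = set()
    for e in events:
        if e.source_author_id == e.retweeter_id:
            continue  # self-retweets excluded
        for aid in (e.source_author_id, e.retweeter_id):
            if types.get(aid) is None:
                untyped.add(aid)
        pairs.append((e.source_author_id, e.retweeter_id))
    if untyped:
        raise ValidationError(
            f"untyped account(s) referenced by interaction events: {sorted(untyped)[:10]}"
        )
    if unique_pairs:
        pairs = sorted(set(pairs))
    counts: dict[tuple[AccountType, AccountType], int] = {}
    for src, tgt in pairs:
        key = (types[src], types[tgt])
        counts[key] = counts.get(key, 0) + 1
    return InteractionMatrix.from_counts(counts)


def matrix_percentages(m: InteractionMatrix) -> tuple[dict[AccountType, float], dict[AccountType, float]]:
    """Row shares (source influence) and column shares (target influence),
    each as percentages of the grand total rounded half-up to 2 dp."""
    if m.grand_total < 1:
        raise UndefinedMetricError("matrix percentages undefined for an empty matrix")
    row_shares = {t: round_half_up(m.row_totals[t] / m.grand_total * 100.0) for t in ACCOUNT_TYPES}
    col_shares = {t: round_half_up(m.col_totals[t] / m.grand_total * 100.0) for t in ACCOUNT_TYPES}
    return row_shares, col_shares


def export_edge_list(m: InteractionMatrix) -> list[dict]:
    """All 16 type-level weighted edges (zero-weight edges kept, flagged)."""
    return [
        {
            "source_type": s.value,
            "target_type": t.value,
            "weight": m.counts[(s, t)],
            "zero_weight": m.counts[(s, t)] == 0,
        }
        for s in ACCOUNT_TYPES
        for t in ACCOUNT_TYPES
    ]


def write_matrix_csv(m: InteractionMatrix, path) -> None:
    """Matrix CSV: one row per source type with per-target cells, the row
    total and row share; a totals row and a column-share row below."""
    row_shares, col_shares = matrix_percentages(m)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["source_type"] + [t.value for t in ACCOUNT_TYPES] + ["total", "share_pct"]
        )
        for s in ACCOUNT_TYPES:
            writer.writerow(
                [s.value]
                + [m.counts[(s, t)] for t in ACCOUNT_TYPES]
                + [m.row_totals[s], f"{row_shares[s]:.2f}"]
            )
        writer.writerow(["total"] + [m.col_totals[t] for t in ACCOUNT_TYPES] + [m.grand_total, ""])
        writer.writerow(
            ["share_pct"] + [f"{col_shares[t]:.2f}" for t in ACCOUNT_TYPES] + ["", ""]
        )


def write_edge_list_csv(m: InteractionMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_type", "target_type", "weight"])
        for edge in export_edge_list(m):
            writer.writerow([edge["source_type"], edge["target_type"], edge["weight"]])


def write_user_edges_csv(events: Iterable[InteractionEvent], path) -> None:
    """Optional per-user directed edge file for graph tooling (deduped)."""
    seen = sorted({(e.source_author_id, e.retweeter_id) for e in events})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "target_id"])
        writer.writerows(seen)
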