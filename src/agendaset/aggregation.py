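"""Per-type influence summaries: totals, percentage shares, rank scaling,
cross-measure averages, and the popularity/influence correlations."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._util import round_half_up
from .core_io import ACCOUNT_TYPES, AccountType
from .errors import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class TypeShareTable:
    """One measure summarized by account type: totals, percentage shares
    (half-up, 2 dp), per-type means, and the grand total."""

    measure_name: str
    per_type_total: dict[AccountType, float]
    per_type_share: dict[AccountType, float]
    per_type_mean: dict[AccountType, float]
    grand_total: float

    def __post_init__(self):
        share_sum = sum(self.per_type_share.values())
        if self.per_type_share and abs(share_sum - 100.0) > 0.05:
            raise ValidationError(
                f"{self.measure_name}: shares sum to {share_sum}, expected 100 +/- 0.05"
            )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    pair_name: str

    def to_json(self) -> str:
        return json.dumps({"pair": self.pair_name, "r": self.r, "n": self.n}, indent=2)


def type_share_table(
    typed_values: Iterable[tuple[AccountType, float]], measure_name: str = ""
) -> TypeShareTable:
    """Summarize one non-negative measure per typed user into a share table."""
    totals = {t: 0.0 for t in ACCOUNT_TYPES}
    counts = {t: 0 for t in ACCOUNT_TYPES}
    for acc_type, value in typed_values:
        if acc_type is None:
            raise ValidationError(f"{measure_name}: untyped user in share table input")
        if value < 0:
            raise ValidationError(f"{measure_name}: negative measure value {value}")
        totals[acc_type] += value
        counts[acc_type] += 1
    grand = sum(totals.values())
    if grand == 0:
        raise UndefinedMetricError(f"{measure_name}: grand total is 0, shares undefined")
    shares = {t: round_half_up(totals[t] / grand * 100.0) for t in ACCOUNT_TYPES}
    means = {t: (totals[t] / counts[t] if counts[t] else 0.0) for t in ACCOUNT_TYPES}
    return TypeShareTable(
        measure_name=measure_name,
        per_type_total=totals,
        per_type_share=shares,
        per_type_mean=means,
        grand_total=grand,
    )


def rank_scale(values: Sequence[float]) -> list[float]:
    """Linear reverse-rank points: the largest of N values scores N, the
    smallest scores 1, and ties share the mean of their tied score span.

    Output always sums to N(N+1)/2. This is one pluggable choice of rank
    scaling; share computations downstream are agnostic to it.
    """
    if len(values) == 0:
        raise ValidationError("rank_scale needs at least one value")
    # ascending average ranks already assign the largest value a score of N
    return [float(s) for s in stats.rankdata(values, method="average")]


def combine_measures(tables: Sequence[TypeShareTable]) -> dict[AccountType, float]:
    """Unweighted mean of per-type percentage shares across measures (2 dp)."""
    if len(tables) < 2:
        raise ValidationError("combine_measures needs >= 2 tables")
    type_sets = [set(t.per_type_share) for t in tables]
    if any(s != type_sets[0] for s in type_sets[1:]):
        raise ValidationError("combine_measures: tables cover different type sets")
    return {
        t: round_half_up(sum(tab.per_type_share[t] for tab in tables) / len(tables))
        for t in sorted(type_sets[0], key=lambda t: t.value)
    }


def pearson_r(x: Sequence[float], y: Sequence[float], pair_name: str = "") -> CorrelationResult:
    """Sample Pearson product-moment correlation between two series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"pearson_r: length mismatch {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValidationError(f"pearson_r needs >= 3 pairs, got {len(x)}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedMetricError("pearson_r undefined: a series has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=len(x), pair_name=pair_name)


def write_share_tables(tables: Sequence[TypeShareTable], path) -> None:
    """Emit a CSV with account-type rows and one column per measure plus the
    cross-measure average."""
    combined = combine_measures(tables) if len(tables) >= 2 else None
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["account_type"] + [f"{t.measure_name}(%)" for t in tables]
        if combined:
            header.append("average(%)")
        writer.writerow(header)
        for acc_type in ACCOUNT_TYPES:
            row = [acc_type.value] + [f"{t.per_type_share[acc_type]:.2f}" for t in tables]
            if combined:
                row.append(f"{combined[acc_type]:.2f}")
            writer.writerow(row)
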