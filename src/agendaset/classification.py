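"""Account typing from coding sheets plus two-rater reliability (Cohen's kappa).

A coding sheet is one rater's mapping of account ids to the four account
types. Reliability is benchmarked on the Fleiss scale: below 0.40 poor,
0.40-0.75 intermediate-good, above 0.75 excellent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from typing import Iterable

from .core_io import AccountRecord, AccountType
from .errors import CoverageError, ValidationError


@dataclass(frozen=True)
class CodingSheet:
    rater_id: str
    assignments: dict[str, AccountType]

    @classmethod
    def from_csv(cls, path, rater_id: str | None = None) -> "CodingSheet":
        """Load a two-column (account_id, account_type) sheet."""
        assignments: dict[str, AccountType] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                aid = row["account_id"]
                if aid in assignments:
                    raise ValidationError(f"{path}: duplicate assignment for account {aid!r}")
                assignments[aid] = AccountType.parse(row["account_type"])
        return cls(rater_id=rater_id or str(path), assignments=assignments)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["account_id", "account_type"])
            for aid in sorted(self.assignments):
                writer.writerow([aid, self.assignments[aid].value])


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int
    benchmark: str
    note: str | None = None

    def to_json(self) -> str:
        d = {
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "n_items": self.n_items,
            "benchmark": self.benchmark,
        }
        if self.note:
            d["note"] = self.note
        return json.dumps(d, indent=2)


def classify_accounts(
    accounts: Iterable[AccountRecord], sheet: CodingSheet, strict: bool = True
) -> list[AccountRecord]:
    """Attach coded types to accounts.

    In strict mode every in-scope account must appear in the sheet; otherwise
    uncoded accounts come back with ``account_type=None`` and are expected to
    be excluded downstream.
    """
    accounts = list(accounts)
    if strict:
        missing = [a.account_id for a in accounts if a.in_scope and a.account_id not in sheet.assignments]
        if missing:
            raise CoverageError(missing)
    return [replace(a, account_type=sheet.assignments.get(a.account_id)) for a in accounts]


def cohen_kappa(sheet_a: CodingSheet, sheet_b: CodingSheet) -> KappaResult:
    """Two-rater Cohen's kappa over the items both sheets cover.

    kappa = (po - pe) / (1 - pe) with po the observed agreement proportion
    and pe the chance agreement from the product of the raters' marginal
    distributions. When both raters assign one identical constant category,
    pe = 1 and kappa is defined as 1 (noted in the result).
    """
    common = sorted(set(sheet_a.assignments) & set(sheet_b.assignments))
    n = len(common)
    if n < 2:
        raise ValidationError(f"cohen_kappa needs >= 2 common items, got {n}")
    cats = list(AccountType)
    po = sum(1 for aid in common if sheet_a.assignments[aid] is sheet_b.assignments[aid]) / n
    marg_a = {c: sum(1 for aid in common if sheet_a.assignments[aid] is c) / n for c in cats}
    marg_b = {c: sum(1 for aid in common if sheet_b.assignments[aid] is c) / n for c in cats}
    pe = sum(marg_a[c] * marg_b[c] for c in cats)
    if pe >= 1.0 - 1e-15:
        kappa, note = 1.0, "both raters constant and identical; kappa defined as 1"
    else:
        kappa, note = (po - pe) / (1.0 - pe), None
    return KappaResult(
        kappa=kappa,
        observed_agreement=po,
        expected_agreement=pe,
        n_items=n,
        benchmark=kappa_benchmark(max(-1.0, min(1.0, kappa))),
        note=note,
    )


def kappa_benchmark(kappa: float) -> str:
    """Fleiss benchmark label for an agreement coefficient.

    Boundaries 0.40 and 0.75 belong to intermediate-good.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.40:
        return "poor"
    if kappa <= 0.75:
        return "intermediate-good"
    return "excellent"
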