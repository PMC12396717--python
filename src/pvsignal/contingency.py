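"""2×2 contingency tables for drug–event disproportionality.

For one drug and one event term, the whole reporting database collapses to

              target term   other terms
    drug           a             b        a+b  (drug's event total)
    comparator     c             d        c+d
                  a+c           b+d       N

where the counting unit is the *event record*: one distinct (case, PT)
pair.  N is the database-wide event-record total, and the comparator is
every other drug's records (by default restricted to primary-suspect
mentions, configurable).  Cells may be non-integral when a table is
reconstructed from published marginals rather than counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

__all__ = ["ContingencyTable", "DatabaseTotals", "database_totals", "build_tables",
           "IntegrityError", "A_MIN"]

#: Minimum case count for a term to be eligible for signal evaluation.
A_MIN = 3


class IntegrityError(ValueError):
    """Inconsistent totals produced a negative derived cell."""


@dataclass(frozen=True)
class ContingencyTable:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise IntegrityError(
                f"negative cell in table (a={self.a}, b={self.b}, c={self.c}, d={self.d})"
            )
        if self.n == 0:
            raise IntegrityError("empty table (N = 0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def p_xy(self) -> float:
        """Joint reporting probability p(x,y) = a/N."""
        return self.a / self.n

    @property
    def p_x(self) -> float:
        """Drug marginal p(x) = (a+b)/N."""
        return (self.a + self.b) / self.n

    @property
    def p_y(self) -> float:
        """Term marginal p(y) = (a+c)/N."""
        return (self.a + self.c) / self.n

    @property
    def eligible(self) -> bool:
        """Case-count threshold a >= 3 shared by all four methods."""
        return self.a >= A_MIN

    def with_continuity(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane-style correction: +k to every cell (opt-in only)."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class DatabaseTotals:
    """Per-term event-record counts over all drugs, plus the grand total."""

    term_counts: Mapping[str, int]
    grand_total: int


def database_totals(
    cases: Sequence,
    level: str = "PT",
    ptsoc=None,
    comparator: str = "ps-only",
) -> DatabaseTotals:
    """Count event records per term over the whole corpus.

    comparator="ps-only" restricts the corpus to cases carrying at least
    one primary-suspect drug mention (the conventional comparator);
    "all-roles" uses every case.
    """
    if comparator not in ("ps-only", "all-roles"):
        raise ValueError(f"unknown comparator mode: {comparator!r}")
    from .target_selection import extract_event_records

    if comparator == "ps-only":
        cases = [c for c in cases if any(m.role == "PS" for m in c.drugs)]
    extraction = extract_event_records(cases, ptsoc=ptsoc)
    df = extraction.records
    key = "pt" if level.upper() == "PT" else "soc"
    counts = df.groupby(key).size().to_dict() if len(df) else {}
    return DatabaseTotals(term_counts=counts, grand_total=len(df))


def build_tables(
    target_records: pd.DataFrame,
    totals: DatabaseTotals,
    level: str = "PT",
) -> Dict[str, ContingencyTable]:
    """One table per term observed for the target drug.

    b = drug total − a;  c = term total − a;  d = N − a − b − c.  Terms the
    drug never reported (a = 0) get no table.  Inconsistent totals (any
    negative derived cell) raise IntegrityError rather than emit a wrong
    table.
    """
    key = "pt" if level.upper() == "PT" else "soc"
    if key not in target_records.columns:
        raise ValueError(f"target records lack a {key!r} column")
    drug_total = len(target_records)
    n = totals.grand_total
    tables: Dict[str, ContingencyTable] = {}
    for term, a in target_records.groupby(key).size().items():
        a = int(a)
        term_total = int(totals.term_counts.get(term, 0))
        b = drug_total - a
        c = term_total - a
        d = n - a - b - c
        try:
            tables[term] = ContingencyTable(a, b, c, d)
        except IntegrityError as exc:
            raise IntegrityError(f"term {term!r}: {exc}") from exc
    return tables
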