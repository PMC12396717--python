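"""Descriptive tabulations: demographics, outcomes, time to onset, annual counts.

Time to onset (TTO) is the number of whole days from the first
primary-suspect therapy start to the report's event date.  Spontaneous
reports carry partial or absent dates routinely, so Unknown is a
first-class bin; a negative difference (event before therapy start) is
treated as data-entry noise and also lands in Unknown.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .faers_ingest import CaseRecord
from .target_selection import SynonymList

__all__ = [
    "ONSET_BINS", "AGE_STRATA", "WEIGHT_STRATA", "OUTCOME_LABELS",
    "time_to_onset", "bin_onset", "summarize", "DemographicsSummary",
]

ONSET_BINS = ["0-30", "31-60", "61-90", "91-120", "121-180", "181-360", ">360", "Unknown"]
_ONSET_EDGES = [(0, 30), (31, 60), (61, 90), (91, 120), (121, 180), (181, 360)]

AGE_STRATA = ["<18", "18-64.9", "65-85", ">85", "Unknown"]
WEIGHT_STRATA = ["<50", "50~100", ">100", "Unknown"]

OUTCOME_LABELS = OrderedDict([
    ("DE", "Death"),
    ("DS", "Disability"),
    ("HO", "Hospitalization"),
    ("LT", "Life-threatening"),
    ("CA", "Congenital anomaly"),
    ("RI", "Required intervention"),
    ("OT", "Other serious outcomes"),
])


def _first_ps_start(case: CaseRecord, synonyms: Optional[SynonymList]):
    for m in case.drugs:  # drugs are drug_seq-ordered at ingest
        if m.role != "PS":
            continue
        if synonyms is not None:
            from .target_selection import _matches
            if not _matches(m, synonyms):
                continue
        return m.therapy_start
    return None


def time_to_onset(case: CaseRecord, synonyms: Optional[SynonymList] = None) -> Optional[int]:
    """Whole days from first PS therapy start to the event date, else None.

    Partial dates (year- or month-precision) cannot support day arithmetic
    and yield None, as do negative differences.
    """
    start = _first_ps_start(case, synonyms)
    if start is None or case.event_dt is None:
        return None
    d0, d1 = start.as_date(), case.event_dt.as_date()
    if d0 is None or d1 is None:
        return None
    days = (d1 - d0).days
    return days if days >= 0 else None


def bin_onset(days: Optional[int]) -> str:
    """Map a day count onto the reporting bins (boundaries label-inclusive)."""
    if days is None or days < 0:
        return "Unknown"
    for lo, hi in _ONSET_EDGES:
        if lo <= days <= hi:
            return f"{lo}-{hi}"
    return ">360"


def _age_stratum(age: Optional[float]) -> str:
    if age is None:
        return "Unknown"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64.9"
    if age <= 85:
        return "65-85"
    return ">85"


def _weight_stratum(w: Optional[float]) -> str:
    if w is None:
        return "Unknown"
    if w < 50:
        return "<50"
    if w <= 100:
        return "50~100"
    return ">100"


Section = "OrderedDict[str, Tuple[int, float]]"  # label -> (count, percent)


def _section(counts: Counter, order: Optional[List[str]] = None) -> OrderedDict:
    labels = order if order is not None else sorted(counts)
    denom = sum(counts[l] for l in labels) or 1
    return OrderedDict((l, (counts[l], 100.0 * counts[l] / denom)) for l in labels)


@dataclass
class DemographicsSummary:
    """Count/percent sections mirroring a standard report-characteristics table.

    Percentages use each section's own tabulated-row sum as denominator.
    Every section partitions the cases except `outcome`, where one case
    contributes to every outcome category it carries (multi-membership).
    """

    n_cases: int
    sex: OrderedDict = field(default_factory=OrderedDict)
    age: OrderedDict = field(default_factory=OrderedDict)
    weight: OrderedDict = field(default_factory=OrderedDict)
    reporter: OrderedDict = field(default_factory=OrderedDict)
    country: OrderedDict = field(default_factory=OrderedDict)
    outcome: OrderedDict = field(default_factory=OrderedDict)
    onset: OrderedDict = field(default_factory=OrderedDict)
    annual: OrderedDict = field(default_factory=OrderedDict)  # year -> count

    def sections(self) -> Dict[str, OrderedDict]:
        return {
            "sex": self.sex, "age": self.age, "weight": self.weight,
            "reporter": self.reporter, "country": self.country,
            "outcome": self.outcome, "onset": self.onset,
        }


def summarize(
    cases: Sequence[CaseRecord], synonyms: Optional[SynonymList] = None
) -> DemographicsSummary:
    """Tabulate demographics, outcomes, onset bins and annual report counts."""
    sex = Counter({"F": 0, "M": 0, "UNK": 0})
    age = Counter({s: 0 for s in AGE_STRATA})
    weight = Counter({s: 0 for s in WEIGHT_STRATA})
    reporter: Counter = Counter()
    country: Counter = Counter()
    outcome: Counter = Counter()
    onset = Counter({b: 0 for b in ONSET_BINS})
    annual: Counter = Counter()

    for case in cases:
        sex[case.sex if case.sex in ("F", "M") else "UNK"] += 1
        age[_age_stratum(case.age_years)] += 1
        weight[_weight_stratum(case.weight_kg)] += 1
        reporter[case.reporter] += 1
        country[case.country] += 1
        if case.outcomes:
            for code in case.outcomes:
                outcome[OUTCOME_LABELS.get(code, code)] += 1
        else:
            outcome["Unknown"] += 1
        onset[bin_onset(time_to_onset(case, synonyms))] += 1
        if case.fda_dt is not None:
            annual[case.fda_dt.year] += 1

    outcome_order = [l for l in OUTCOME_LABELS.values() if outcome[l]] + (
        ["Unknown"] if outcome["Unknown"] else []
    )
    return DemographicsSummary(
        n_cases=len(cases),
        sex=_section(sex, ["F", "M", "UNK"]),
        age=_section(age, AGE_STRATA),
        weight=_section(weight, WEIGHT_STRATA),
        reporter=_section(reporter),
        country=_section(country),
        outcome=_section(outcome, outcome_order),
        onset=_section(onset, ONSET_BINS),
        annual=OrderedDict(sorted(annual.items())),
    )


def summary_frame(summary: DemographicsSummary):
    """Long-form (section, label, count, percent) frame for TSV export."""
    import pandas as pd

    rows = []
    for name, sec in summary.sections().items():
        for label, (count, pct) in sec.items():
            rows.append((name, str(label), count, round(pct, 2)))
    return pd.DataFrame(rows, columns=["section", "label", "count", "percent"])
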