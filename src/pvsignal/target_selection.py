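"""Selecting the target drug's primary-suspect reports and their event terms.

A spontaneous report names the same product under many spellings, so the
target drug is defined by a user-supplied synonym list (brand name, active
ingredient, formulation variants).  A case is *selected* when at least one
of its drug mentions carries the primary-suspect (PS) role code and its
name — verbatim or active ingredient — matches the synonym list after
normalisation.  Event terms are MedDRA Preferred Terms (PTs); each distinct
(case, PT) pair is one *event record*, the counting unit of every
downstream statistic.  PTs are annotated with their primary System Organ
Class (SOC) from a user-supplied map, and indication-related PTs (e.g. the
procedure the contrast agent is used for) are excluded before any
statistic is computed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SynonymList",
    "PtSocMap",
    "ExclusionList",
    "normalize_name",
    "normalize_pt",
    "select_primary_suspect",
    "extract_event_records",
    "EventExtraction",
]

_PUNCT = re.compile(r"[.,;:/\\()\[\]\-]")
_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonical drug-name form: uppercase, punctuation stripped, whitespace
    collapsed.  Matching is exact on this form — no fuzzy matching."""
    s = _PUNCT.sub(" ", str(raw))
    return _WS.sub(" ", s).strip().upper()


def normalize_pt(raw: str) -> str:
    """Canonical PT form for case-insensitive matching (whitespace collapse +
    uppercase; PT punctuation is meaningful and kept)."""
    return _WS.sub(" ", str(raw)).strip().upper()


class ConfigError(ValueError):
    """Unusable user configuration (e.g. empty synonym list)."""


@dataclass(frozen=True)
class SynonymList:
    """Normalized names identifying the target drug."""

    entries: frozenset

    def __post_init__(self):
        if not self.entries:
            raise ConfigError("synonym list is empty; cannot select target reports")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "SynonymList":
        return cls(frozenset(normalize_name(n) for n in names if str(n).strip()))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SynonymList":
        return cls.from_names(Path(path).read_text().splitlines())

    def __contains__(self, name: object) -> bool:
        return normalize_name(str(name)) in self.entries


@dataclass(frozen=True)
class PtSocMap:
    """PT -> primary SOC mapping (each PT has exactly one primary SOC)."""

    mapping: dict
    version: str = "unversioned"

    @classmethod
    def from_pairs(cls, pairs: Iterable, version: str = "unversioned") -> "PtSocMap":
        return cls({normalize_pt(pt): str(soc).strip() for pt, soc in pairs}, version)

    @classmethod
    def from_file(cls, path: Union[str, Path], version: Optional[str] = None) -> "PtSocMap":
        """Two-column TSV (PT, SOC), no header required; '#' comments allowed."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                logger.warning("pt-soc map: skipping malformed line %r", line)
                continue
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs, version or Path(path).name)

    def soc_of(self, pt: str) -> Optional[str]:
        return self.mapping.get(normalize_pt(pt))


@dataclass(frozen=True)
class ExclusionList:
    """PTs dropped as indication artifacts (may be empty)."""

    entries: frozenset = frozenset()

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "ExclusionList":
        return cls(frozenset(normalize_pt(n) for n in names if str(n).strip()))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ExclusionList":
        return cls.from_names(Path(path).read_text().splitlines())

    def __contains__(self, pt: object) -> bool:
        return normalize_pt(str(pt)) in self.entries


def _matches(mention, synonyms: SynonymList) -> bool:
    if mention.verbatim_name and mention.verbatim_name in synonyms:
        return True
    return bool(mention.active_ingredient and mention.active_ingredient in synonyms)


def select_primary_suspect(cases: Sequence, synonyms: SynonymList) -> list:
    """Cases where the target drug appears with role PS.

    A case carrying the drug only as secondary suspect, concomitant or
    interacting is excluded.  Monotone in the synonym list: adding names
    can only add cases.
    """
    if not isinstance(synonyms, SynonymList):
        synonyms = SynonymList.from_names(synonyms)
    return [
        c for c in cases
        if any(m.role == "PS" and _matches(m, synonyms) for m in c.drugs)
    ]


@dataclass
class EventExtraction:
    """Event records plus exclusion bookkeeping."""

    records: pd.DataFrame  # columns: caseid, pt, soc (pt normalized)
    n_excluded: int = 0
    unmapped_pts: set = field(default_factory=set)

    @property
    def total(self) -> int:
        """The drug's event-record total (every statistic's a+b)."""
        return len(self.records)


def extract_event_records(
    cases: Sequence,
    ptsoc: Optional[PtSocMap] = None,
    exclusions: Optional[ExclusionList] = None,
) -> EventExtraction:
    """One event record per distinct (caseid, PT) pair across the cases.

    A PT repeated within one report counts once; the same PT on different
    cases counts once per case.  Excluded PTs are dropped (and counted)
    before anything downstream sees them.  PTs absent from the SOC map are
    kept under SOC "UNMAPPED" so totals are conserved.
    """
    exclusions = exclusions or ExclusionList()
    rows = []
    n_excluded = 0
    unmapped = set()
    for case in cases:
        for pt in sorted({normalize_pt(p) for p in case.events if str(p).strip()}):
            if pt in exclusions.entries:
                n_excluded += 1
                continue
            soc = ptsoc.soc_of(pt) if ptsoc is not None else None
            if soc is None:
                unmapped.add(pt)
                soc = "UNMAPPED"
            rows.append((case.caseid, pt, soc))
    if unmapped:
        logger.warning("%d PT(s) missing from the SOC map; kept as UNMAPPED", len(unmapped))
    df = pd.DataFrame(rows, columns=["caseid", "pt", "soc"])
    return EventExtraction(df, n_excluded=n_excluded, unmapped_pts=unmapped)
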