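"""Reading, normalising and deduplicating FAERS-style quarterly extracts.

FAERS ships each quarter as seven "$"-delimited ASCII tables (DEMO, DRUG,
REAC, THER, OUTC, INDI, RPSR).  Two layouts exist: the legacy one keys
reports by ISR/CASE, the modern one by PRIMARYID/CASEID.  A *report*
(primaryid) is one version of a *case* (caseid); the database re-publishes
cases as follow-up versions arrive, so the same caseid appears under
several primaryids and FDA receipt dates.  Deduplication keeps, per caseid,
the version with the latest FDA_DT, breaking ties by the numerically
greater primaryid.
"""

from __future__ import annotations

import datetime as _dt
import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FaersDate",
    "DrugMention",
    "CaseRecord",
    "QuarterlyFileSet",
    "IngestResult",
    "parse_faers_date",
    "normalize_age",
    "normalize_weight",
    "read_quarter",
    "deduplicate",
]

#: OCCP_COD -> reporter category (mirrors the demographic table rows).
REPORTER_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "HP": "health-professional",
    "RN": "registered-nurse",
    "LW": "lawyer",
}

#: Patient-outcome codes carried by the OUTC table.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: AGE_COD -> factor converting to years.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WEIGHT_FACTORS = {"KG": 1.0, "LBS": 0.453592, "GMS": 1e-3}


class IngestError(RuntimeError):
    """Fatal problem with a quarterly file set (missing file, unknown layout)."""


@dataclass(frozen=True)
class FaersDate:
    """A possibly partial FAERS date (YYYY, YYYYMM or YYYYMMDD).

    Partial dates keep their year for annual tabulations but refuse to take
    part in day-difference arithmetic (``as_date()`` returns None).
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def as_date(self) -> Optional[_dt.date]:
        if not self.is_complete:
            return None
        try:
            return _dt.date(self.year, self.month, self.day)
        except ValueError:
            return None

    def sort_key(self) -> int:
        """Integer YYYYMMDD with zeros for missing components (dedup ordering)."""
        return self.year * 10000 + (self.month or 0) * 100 + (self.day or 0)


def parse_faers_date(raw: object) -> Optional[FaersDate]:
    """Parse a FAERS date string; returns None for blank/garbled values."""
    if raw is None:
        return None
    s = str(raw).strip()
    if s.endswith(".0"):  # numeric round-trip artifact
        s = s[:-2]
    if not s.isdigit():
        return None
    if len(s) == 4:
        return FaersDate(int(s))
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        return FaersDate(y, m) if 1 <= m <= 12 else FaersDate(y)
    if len(s) == 8:
        d = FaersDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if d.as_date() is None:
            return FaersDate(d.year)  # impossible day: degrade to year
        return d
    return None


@dataclass(frozen=True)
class DrugMention:
    """One DRUG-table row: a drug as reported on a case."""

    verbatim_name: str
    role: str  # PS | SS | C | I
    drug_seq: int
    active_ingredient: Optional[str] = None
    therapy_start: Optional[FaersDate] = None


@dataclass
class CaseRecord:
    """One safety report (one DEMO row joined to its child tables)."""

    primaryid: str
    caseid: str
    fda_dt: Optional[FaersDate]
    event_dt: Optional[FaersDate] = None
    sex: str = "UNK"  # F | M | UNK
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    reporter: str = "unknown"
    country: str = "unknown"
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    events: set = field(default_factory=set)


@dataclass
class QuarterlyFileSet:
    """Paths (or text streams) of one quarter's FAERS tables.

    DEMO, DRUG and REAC are required; the rest are optional and their
    absence is logged rather than fatal.
    """

    demo: Union[str, Path, io.TextIOBase]
    drug: Union[str, Path, io.TextIOBase]
    reac: Union[str, Path, io.TextIOBase]
    ther: Optional[Union[str, Path, io.TextIOBase]] = None
    outc: Optional[Union[str, Path, io.TextIOBase]] = None
    indi: Optional[Union[str, Path, io.TextIOBase]] = None
    rpsr: Optional[Union[str, Path, io.TextIOBase]] = None
    layout_version: str = "modern"  # modern | legacy

    def __post_init__(self) -> None:
        if self.layout_version not in ("modern", "legacy"):
            raise IngestError(f"unknown layout version: {self.layout_version!r}")


@dataclass
class IngestResult:
    """Parsed records plus the bookkeeping the audit trail needs."""

    records: list
    malformed: dict = field(default_factory=dict)  # table -> [(line_no, line)]
    orphans: dict = field(default_factory=dict)  # table -> count
    keyless_dropped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def normalize_age(value: object, unit_code: object) -> Optional[float]:
    """Convert an (age, AGE_COD) pair to years.

    A blank unit with a numeric value is taken as years.  Non-physical
    results (negative or >150 y) coerce to missing with a warning.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    unit = str(unit_code).strip().upper() if unit_code is not None else ""
    if unit in ("", "NAN", "NONE"):
        factor = 1.0
    elif unit in _AGE_FACTORS:
        factor = _AGE_FACTORS[unit]
    else:
        logger.warning("unrecognised age unit %r; treating age as missing", unit_code)
        return None
    years = v * factor
    if years < 0 or years > 150:
        logger.warning("non-physical age %r %s; treating as missing", value, unit)
        return None
    return years


def normalize_weight(value: object, unit_code: object) -> Optional[float]:
    """Convert a (weight, WT_COD) pair to kilograms; blank unit means kg."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    unit = str(unit_code).strip().upper() if unit_code is not None else ""
    if unit in ("", "NAN", "NONE"):
        factor = 1.0
    elif unit in _WEIGHT_FACTORS:
        factor = _WEIGHT_FACTORS[unit]
    else:
        logger.warning("unrecognised weight unit %r; treating weight as missing", unit_code)
        return None
    kg = v * factor
    if kg <= 0 or kg > 700:
        logger.warning("non-physical weight %r %s; treating as missing", value, unit)
        return None
    return kg


# ---------------------------------------------------------------------------
# file parsing

_LEGACY_RENAMES = {"isr": "primaryid", "case": "caseid", "gndr_cod": "sex"}


def _scan_bad_lines(text: str) -> list:
    """1-based line numbers (and content) of rows whose '$' field count
    differs from the header's. pandas skips them; we must still report them."""
    lines = text.splitlines()
    if not lines:
        return []
    want = lines[0].count("$")
    return [
        (i, ln)
        for i, ln in enumerate(lines[1:], start=2)
        if ln.strip() and ln.count("$") != want
    ]


def _read_table(source, table: str, malformed: dict) -> Optional[pd.DataFrame]:
    if source is None:
        return None
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    bad = _scan_bad_lines(text)
    if bad:
        malformed[table] = bad
        logger.warning("%s: quarantined %d malformed line(s): %s",
                       table, len(bad), [n for n, _ in bad[:10]])
    try:
        df = pd.read_csv(
            io.StringIO(text), sep="$", dtype=str, engine="python",
            skiprows=[n - 1 for n, _ in bad],
        )
    except pd.errors.EmptyDataError:
        return None
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_LEGACY_RENAMES)
    return df


def _clean(val: object) -> Optional[str]:
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return None
    s = str(val).strip()
    return s or None


def read_quarter(fileset: QuarterlyFileSet) -> IngestResult:
    """Assemble one CaseRecord per DEMO row, joining child tables by report key.

    DRUG joins on primaryid, REAC on primaryid, THER on (primaryid,
    drug_seq), OUTC on primaryid.  Legacy ISR/CASE columns are mapped onto
    primaryid/caseid.  Child rows whose report key has no DEMO row are
    orphans: counted, logged, excluded.
    """
    malformed: dict = {}
    demo = _read_table(fileset.demo, "DEMO", malformed)
    if demo is None or demo.empty:
        raise IngestError("DEMO file missing or empty; cannot assemble records")
    drug = _read_table(fileset.drug, "DRUG", malformed)
    reac = _read_table(fileset.reac, "REAC", malformed)
    if drug is None or reac is None:
        raise IngestError("DRUG and REAC files are required")
    ther = _read_table(fileset.ther, "THER", malformed)
    outc = _read_table(fileset.outc, "OUTC", malformed)
    for name, src in (("THER", fileset.ther), ("OUTC", fileset.outc),
                      ("INDI", fileset.indi), ("RPSR", fileset.rpsr)):
        if src is None:
            logger.info("%s file absent; continuing without it", name)

    for required_col, df, table in (("primaryid", demo, "DEMO"),
                                    ("primaryid", drug, "DRUG"),
                                    ("primaryid", reac, "REAC")):
        if required_col not in df.columns:
            raise IngestError(
                f"{table} lacks a {required_col}/ISR column; unknown layout"
            )

    known = set(demo["primaryid"].dropna().astype(str).str.strip())
    orphans: dict = {}

    def _group(df: Optional[pd.DataFrame], table: str):
        if df is None or df.empty:
            return {}
        keys = df["primaryid"].astype(str).str.strip()
        orphan_mask = ~keys.isin(known)
        n_orphan = int(orphan_mask.sum())
        if n_orphan:
            orphans[table] = n_orphan
            logger.warning("%s: %d orphan row(s) with no DEMO report", table, n_orphan)
        return dict(tuple(df[~orphan_mask].groupby(keys[~orphan_mask])))

    drug_by_id = _group(drug, "DRUG")
    reac_by_id = _group(reac, "REAC")
    ther_by_id = _group(ther, "THER") if ther is not None else {}
    outc_by_id = _group(outc, "OUTC") if outc is not None else {}

    records = []
    keyless = 0
    for row in demo.itertuples(index=False):
        rd = row._asdict()
        pid = _clean(rd.get("primaryid"))
        cid = _clean(rd.get("caseid"))
        if pid is None and cid is None:
            keyless += 1
            continue
        pid = pid if pid is not None else cid
        cid = cid if cid is not None else pid

        sex = (_clean(rd.get("sex")) or "").upper()
        country = _clean(rd.get("reporter_country")) or _clean(rd.get("occr_country"))
        occp = (_clean(rd.get("occp_cod")) or "").upper()

        mentions = []
        ther_rows = ther_by_id.get(pid)
        starts: Mapping[str, Optional[FaersDate]] = {}
        if ther_rows is not None:
            seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther_rows.columns else "drug_seq"
            starts = {
                _clean(t[seq_col]): parse_faers_date(t.get("start_dt"))
                for _, t in ther_rows.iterrows()
            }
        drug_rows = drug_by_id.get(pid)
        if drug_rows is not None:
            for _, d in drug_rows.iterrows():
                seq_raw = _clean(d.get("drug_seq")) or "0"
                try:
                    seq = int(float(seq_raw))
                except ValueError:
                    seq = 0
                mentions.append(
                    DrugMention(
                        verbatim_name=_clean(d.get("drugname")) or "",
                        active_ingredient=_clean(d.get("prod_ai")),
                        role=(_clean(d.get("role_cod")) or "").upper(),
                        drug_seq=seq,
                        therapy_start=starts.get(seq_raw),
                    )
                )
            mentions.sort(key=lambda m: m.drug_seq)

        events = set()
        reac_rows = reac_by_id.get(pid)
        if reac_rows is not None:
            events = {p for p in (_clean(x) for x in reac_rows["pt"]) if p}

        outcomes: frozenset = frozenset()
        outc_rows = outc_by_id.get(pid)
        if outc_rows is not None:
            outcomes = frozenset(
                c for c in ((_clean(x) or "").upper() for x in outc_rows["outc_cod"])
                if c in OUTCOME_CODES
            )

        records.append(
            CaseRecord(
                primaryid=pid,
                caseid=cid,
                fda_dt=parse_faers_date(rd.get("fda_dt")),
                event_dt=parse_faers_date(rd.get("event_dt")),
                sex=sex if sex in ("F", "M") else "UNK",
                age_years=normalize_age(rd.get("age"), rd.get("age_cod")),
                weight_kg=normalize_weight(rd.get("wt"), rd.get("wt_cod")),
                reporter=REPORTER_CODES.get(occp, "unknown"),
                country=country or "unknown",
                outcomes=outcomes,
                drugs=mentions,
                events=events,
            )
        )
    if keyless:
        logger.warning("DEMO: dropped %d row(s) lacking both report keys", keyless)
    return IngestResult(records, malformed=malformed, orphans=orphans,
                        keyless_dropped=keyless)


def read_quarters(filesets: Iterable[QuarterlyFileSet]) -> IngestResult:
    """Pool several quarters into one record list (dedup is applied later,
    across the pooled corpus, because caseids recur between quarters)."""
    pooled = IngestResult([])
    for fs in filesets:
        res = read_quarter(fs)
        pooled.records.extend(res.records)
        for k, v in res.malformed.items():
            pooled.malformed.setdefault(k, []).extend(v)
        for k, v in res.orphans.items():
            pooled.orphans[k] = pooled.orphans.get(k, 0) + v
        pooled.keyless_dropped += res.keyless_dropped
    return pooled


def _primaryid_key(pid: str):
    # FAERS ids are numeric strings; compare numerically, falling back to a
    # lexical ordering for non-numeric ids so ties still break deterministically.
    return (1, int(pid), "") if pid.isdigit() else (0, 0, pid)


def deduplicate(records: Sequence[CaseRecord]) -> list:
    """One record per caseid: latest FDA_DT wins, ties go to the greater
    PRIMARYID.  Idempotent; input order does not affect the outcome."""
    best: dict = {}
    for rec in records:
        cid = rec.caseid or rec.primaryid
        if not cid:
            logger.warning("dropping record with neither caseid nor primaryid")
            continue
        key = (rec.fda_dt.sort_key() if rec.fda_dt else 0, _primaryid_key(rec.primaryid))
        incumbent = best.get(cid)
        if incumbent is None or key > incumbent[0]:
            best[cid] = (key, rec)
    return [rec for _, rec in best.values()]
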