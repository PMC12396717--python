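"""Shared fixtures: tiny in-memory FAERS file sets and record factories."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

from pvsignal.faers_ingest import CaseRecord, DrugMention, FaersDate

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


def make_case(
    caseid: str = "100",
    primaryid: str | None = None,
    fda: str = "20230101",
    event: str | None = None,
    sex: str = "F",
    age: float | None = 60.0,
    weight: float | None = 80.0,
    drugs: list | None = None,
    events: set | None = None,
    outcomes: frozenset = frozenset(),
    reporter: str = "consumer",
    country: str = "US",
) -> CaseRecord:
    from pvsignal.faers_ingest import parse_faers_date

    return CaseRecord(
        primaryid=primaryid if primaryid is not None else caseid + "1",
        caseid=caseid,
        fda_dt=parse_faers_date(fda),
        event_dt=parse_faers_date(event) if event else None,
        sex=sex,
        age_years=age,
        weight_kg=weight,
        reporter=reporter,
        country=country,
        outcomes=outcomes,
        drugs=drugs if drugs is not None else [ps_mention()],
        events=events if events is not None else {"Back pain"},
    )


def ps_mention(
    name: str = "DEFINITY",
    role: str = "PS",
    seq: int = 1,
    start: str | None = None,
) -> DrugMention:
    from pvsignal.faers_ingest import parse_faers_date

    return DrugMention(
        verbatim_name=name,
        role=role,
        drug_seq=seq,
        active_ingredient=None,
        therapy_start=parse_faers_date(start) if start else None,
    )


@pytest.fixture
def tiny_quarter(tmp_path):
    """Three modern-layout reports: one with two PTs, one duplicate pair."""
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country$occr_country\n"
        "11$1$20230101$20230116$F$60$YR$154$LBS$CN$US$US\n"
        "21$2$20230201$20230202$M$5$DEC$70$KG$MD$US$US\n"
        "31$3$20230301$$UNKSEX$24$MON$$$OT$CA$CA\n"
    )
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$drug_seq$role_cod$drugname$prod_ai\n"
        "11$1$PS$DEFINITY$PERFLUTREN\n"
        "21$1$PS$Definity (perflutren)$\n"
        "21$2$C$ASPIRIN$ASPIRIN\n"
        "31$1$SS$DEFINITY$\n"
        "99$1$PS$ORPHANED$\n"
    )
    (tmp_path / "REAC.txt").write_text(
        "primaryid$pt\n"
        "11$Back pain\n"
        "11$Dyspnoea\n"
        "21$Back pain\n"
        "31$Flushing\n"
    )
    (tmp_path / "THER.txt").write_text(
        "primaryid$dsg_drug_seq$start_dt\n"
        "11$1$20230101\n"
        "21$1$20230115\n"
    )
    (tmp_path / "OUTC.txt").write_text(
        "primaryid$outc_cod\n"
        "11$HO\n"
        "11$LT\n"
        "21$DE\n"
    )
    return tmp_path
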