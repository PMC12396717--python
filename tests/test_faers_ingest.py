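"""Parsing, unit normalisation and case deduplication."""

from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from pvsignal import faers_ingest as fi


class TestUnitNormalisation:
    @pytest.mark.parametrize(
        ("value", "unit", "expected"),
        [
            (5, "DEC", 50.0),
            (30, "YR", 30.0),
            (24, "MON", 2.0),
            (52.1775, "WK", 1.0),
            (365.25, "DY", 1.0),
            (8766, "HR", 1.0),
            (42, "", 42.0),  # blank unit read as years
            (-3, "YR", None),
            (200, "YR", None),  # beyond plausible lifespan
            ("", "YR", None),
            (30, "LightYR", None),
        ],
    )
    def test_age(self, value, unit, expected):
        got = fi.normalize_age(value, unit)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize(
        ("value", "unit", "expected"),
        [
            (154, "LBS", 154 * 0.453592),
            (70, "KG", 70.0),
            (70000, "GMS", 70.0),
            (80, "", 80.0),
            (-5, "KG", None),
            (0, "KG", None),
            (9000, "KG", None),
        ],
    )
    def test_weight(self, value, unit, expected):
        got = fi.normalize_weight(value, unit)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestDateParsing:
    def test_full_partial_and_garbled(self):
        full = fi.parse_faers_date("20230116")
        assert full.as_date().isoformat() == "2023-01-16"
        assert fi.parse_faers_date("202301").as_date() is None
        assert fi.parse_faers_date("202301").year == 2023
        assert fi.parse_faers_date("2023").year == 2023
        assert fi.parse_faers_date("") is None
        assert fi.parse_faers_date("20231399").month is None  # impossible day


class TestReadQuarter:
    def test_joins_demo_drug_reac(self, tiny_quarter):
        fs = fi.QuarterlyFileSet(
            demo=tiny_quarter / "DEMO.txt",
            drug=tiny_quarter / "DRUG.txt",
            reac=tiny_quarter / "REAC.txt",
            ther=tiny_quarter / "THER.txt",
            outc=tiny_quarter / "OUTC.txt",
        )
        result = fi.read_quarter(fs)
        assert len(result) == 3
        by_id = {r.primaryid: r for r in result}
        assert by_id["11"].events == {"Back pain", "Dyspnoea"}
        assert by_id["11"].weight_kg == pytest.approx(154 * 0.453592)
        assert by_id["11"].outcomes == {"HO", "LT"}
        assert by_id["11"].drugs[0].therapy_start.as_date().isoformat() == "2023-01-01"
        assert by_id["21"].age_years == 50.0  # 5 decades
        assert by_id["21"].reporter == "physician"
        assert by_id["31"].sex == "UNK"
        assert by_id["31"].age_years == pytest.approx(2.0)
        # DRUG row keyed 99 has no DEMO report: counted, excluded
        assert result.orphans == {"DRUG": 1}

    def test_legacy_isr_case_mapping(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "ISR$CASE$FDA_DT$EVENT_DT$GNDR_COD$AGE$AGE_COD$WT$WT_COD$OCCP_COD$REPORTER_COUNTRY$OCCR_COUNTRY\n"
            "7001$700$20080101$$M$40$YR$$$CN$US$US\n"
        )
        (tmp_path / "DRUG.txt").write_text(
            "ISR$DRUG_SEQ$ROLE_COD$DRUGNAME$PROD_AI\n7001$1$PS$DEFINITY$\n"
        )
        (tmp_path / "REAC.txt").write_text("ISR$PT\n7001$Headache\n")
        fs = fi.QuarterlyFileSet(
            demo=tmp_path / "DEMO.txt", drug=tmp_path / "DRUG.txt",
            reac=tmp_path / "REAC.txt", layout_version="legacy",
        )
        [rec] = fi.read_quarter(fs).records
        assert rec.primaryid == "7001"
        assert rec.caseid == "700"
        assert rec.sex == "M"

    def test_malformed_row_quarantined_with_line_number(self, tiny_quarter):
        (tiny_quarter / "REAC.txt").write_text(
            "primaryid$pt\n11$Back pain\n11$Too$Many$Fields\n21$Nausea\n"
        )
        fs = fi.QuarterlyFileSet(
            demo=tiny_quarter / "DEMO.txt", drug=tiny_quarter / "DRUG.txt",
            reac=tiny_quarter / "REAC.txt",
        )
        result = fi.read_quarter(fs)
        assert [n for n, _ in result.malformed["REAC"]] == [3]
        assert {r.primaryid: r.events for r in result}["21"] == {"Nausea"}

    def test_missing_demo_is_fatal(self, tiny_quarter):
        (tiny_quarter / "DEMO.txt").write_text("")
        fs = fi.QuarterlyFileSet(
            demo=tiny_quarter / "DEMO.txt", drug=tiny_quarter / "DRUG.txt",
            reac=tiny_quarter / "REAC.txt",
        )
        with pytest.raises(fi.IngestError):
            fi.read_quarter(fs)

    def test_unknown_layout_is_fatal(self, tiny_quarter):
        with pytest.raises(fi.IngestError):
            fi.QuarterlyFileSet(
                demo=tiny_quarter / "DEMO.txt", drug=tiny_quarter / "DRUG.txt",
                reac=tiny_quarter / "REAC.txt", layout_version="quarterly",
            )


class TestDeduplicate:
    def _rec(self, caseid, primaryid, fda):
        from conftest import make_case

        return make_case(caseid=caseid, primaryid=primaryid, fda=fda)

    def test_latest_fda_dt_wins(self):
        kept = fi.deduplicate(
            [self._rec("100", "1001", "20230101"), self._rec("100", "1002", "20230301")]
        )
        assert [r.primaryid for r in kept] == ["1002"]

    def test_fda_tie_broken_by_higher_primaryid(self):
        kept = fi.deduplicate(
            [self._rec("100", "1002", "20230101"), self._rec("100", "1001", "20230101")]
        )
        assert [r.primaryid for r in kept] == ["1002"]

    def test_numeric_not_lexical_comparison(self):
        kept = fi.deduplicate(
            [self._rec("100", "900", "20230101"), self._rec("100", "1002", "20230101")]
        )
        assert [r.primaryid for r in kept] == ["1002"]

    def test_distinct_caseids_both_retained(self):
        kept = fi.deduplicate([self._rec("100", "1001", "20230101"),
                               self._rec("200", "2001", "20230101")])
        assert {r.caseid for r in kept} == {"100", "200"}

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 30),  # caseid
                st.integers(1, 9999),  # primaryid
                st.integers(20200101, 20240101),  # fda_dt
            ),
            max_size=60,
        )
    )
    def test_idempotent_and_one_record_per_caseid(self, triples):
        from conftest import make_case

        records = [
            make_case(caseid=str(c), primaryid=str(p), fda=str(f))
            for c, p, f in triples
        ]
        once = fi.deduplicate(records)
        assert len(once) == len({r.caseid for r in records})
        twice = fi.deduplicate(once)
        assert {(r.caseid, r.primaryid) for r in twice} == {
            (r.caseid, r.primaryid) for r in once
        }
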