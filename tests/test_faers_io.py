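"""Parsing, unit normalization and case de-duplication."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faerspv
from faerspv.faers_io import (InputError, ReportStore, SchemaError,
                              normalize_age_years, normalize_weight_kg)
from tests.conftest import (DEMO_HEADER, DRUG_HEADER, OUTC_HEADER, REAC_HEADER,
                            write_faers)


@pytest.mark.parametrize("value,code,expected", [
    ("67", "YR", 67.0),
    ("670", "MON", 670 / 12),
    ("7", "DEC", 70.0),
    ("14", "WK", 14 / 52.1775),
    ("730.5", "DY", 2.0),
    ("8766", "HR", 1.0),
    ("67", "XX", None),       # unknown unit code
    ("abc", "YR", None),      # unparseable value
    ("", "YR", None),
    ("200", "YR", None),      # outside the plausible range
    ("-5", "YR", None),
])
def test_age_normalization(value, code, expected):
    got = normalize_age_years(value, code)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


@pytest.mark.parametrize("value,code,expected", [
    ("59", "KG", 59.0),
    ("154", "LBS", 154 * 0.453592),
    ("70000", "GMS", 70.0),
    ("80", "??", None),
    ("x", "KG", None),
    ("0", "KG", None),        # nonphysical
    ("700", "KG", None),
])
def test_weight_normalization(value, code, expected):
    got = normalize_weight_kg(value, code)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(st.text(max_size=12), st.text(max_size=6))
def test_unit_normalization_is_total(value, code):
    """Any (value, code) pair maps to a float or None, never an exception."""
    for fn in (normalize_age_years, normalize_weight_kg):
        out = fn(value, code)
        assert out is None or isinstance(out, float)


class TestParsing:
    def test_field_mapping(self, tiny_store):
        rec = {r.primaryid: r for r in tiny_store}["1001"]
        assert rec.caseid == "100"
        assert rec.fda_dt == "20240101"
        assert rec.sex == "F"
        assert rec.age_years == 67.0
        assert rec.weight_kg == 59.0
        assert rec.reporter_type == "physician"
        assert rec.events == {"Rash", "Dry skin"}
        assert rec.outcomes == {"DE", "HO"}
        assert len(rec.drugs) == 1
        assert rec.indications == [(1, "NON-SMALL CELL LUNG CANCER")]

    def test_unit_conversion_applied_on_read(self, tiny_store):
        rec = {r.primaryid: r for r in tiny_store}["1002"]
        assert rec.age_years == pytest.approx(670 / 12)
        assert rec.weight_kg == pytest.approx(69.853168, abs=1e-6)

    def test_missing_fields_stay_missing(self, tiny_store):
        rec = {r.primaryid: r for r in tiny_store}["1003"]
        assert rec.age_years is None and rec.weight_kg is None
        assert rec.reporter_country is None
        rec4 = {r.primaryid: r for r in tiny_store}["1004"]
        assert rec4.sex == "unknown" and rec4.reporter_type == "missing"

    def test_missing_column_names_file_and_column(self, tmp_path):
        paths = write_faers(tmp_path, {
            "DEMO": ["primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod",
                     "1$1$20240101$F$60$YR$70$KG$MD"]})
        with pytest.raises(SchemaError, match="reporter_country"):
            faerspv.read_faers_tables(paths)

    def test_empty_demo_is_input_error(self, tmp_path):
        paths = write_faers(tmp_path, {"DEMO": [DEMO_HEADER]})
        with pytest.raises(InputError):
            faerspv.read_faers_tables(paths)

    def test_no_demo_is_schema_error(self, tmp_path):
        paths = write_faers(tmp_path, {"REAC": [REAC_HEADER, "1$Rash"]})
        with pytest.raises(SchemaError, match="DEMO"):
            faerspv.read_faers_tables(paths)

    def test_malformed_rows_rejected_and_counted(self, tmp_path):
        paths = write_faers(tmp_path, {
            "DEMO": [DEMO_HEADER,
                     "1001$100$20240101$F$67$YR$59$KG$MD$US",
                     "bad$row$with$too$few"],
            "REAC": [REAC_HEADER, "1001$Rash", "1001$Extra$Field"],
        })
        store = faerspv.read_faers_tables(paths)
        assert len(store) == 1
        by_table = {e["table"]: e for e in store.provenance}
        assert by_table["DEMO"]["rejected"] == 1
        assert by_table["REAC"]["rejected"] == 1
        store.check_provenance()

    def test_join_orphans_dropped_and_counted(self, tmp_path):
        paths = write_faers(tmp_path, {
            "DEMO": [DEMO_HEADER, "1001$100$20240101$F$67$YR$59$KG$MD$US"],
            "DRUG": [DRUG_HEADER, "1001$1$PS$TAGRISSO$OSIMERTINIB",
                     "9999$1$PS$GHOST$GHOST"],
        })
        store = faerspv.read_faers_tables(paths)
        drug_prov = next(e for e in store.provenance if e["table"] == "DRUG")
        assert drug_prov["orphans"] == 1
        assert len(store.reports[0].drugs) == 1

    def test_legacy_schema_rejected(self, tmp_path):
        paths = write_faers(tmp_path, {"DEMO": [DEMO_HEADER]})
        with pytest.raises(SchemaError, match="schema"):
            faerspv.read_faers_tables(paths, schema_version="laers")

    def test_duplicate_pt_counts_once(self, tmp_path):
        paths = write_faers(tmp_path, {
            "DEMO": [DEMO_HEADER, "1001$100$20240101$F$67$YR$59$KG$MD$US"],
            "REAC": [REAC_HEADER, "1001$Rash", "1001$Rash"],
        })
        store = faerspv.read_faers_tables(paths)
        assert store.reports[0].events == {"Rash"}


def _mkrec(primaryid, caseid, fda_dt):
    return faerspv.ReportRecord(
        primaryid=primaryid, caseid=caseid, fda_dt=fda_dt, sex="F",
        age_years=None, weight_kg=None, reporter_country=None,
        reporter_type="missing", outcomes=frozenset(), drugs=[],
        events=frozenset(), indications=[])


class TestDeduplicate:
    def test_keeps_most_recent_date(self):
        store = ReportStore(reports=[_mkrec("1001", "100", "20240101"),
                                     _mkrec("1002", "100", "20240301")])
        out = faerspv.deduplicate(store)
        assert [r.primaryid for r in out] == ["1002"]

    def test_ties_resolved_by_larger_primaryid(self):
        store = ReportStore(reports=[_mkrec("1003", "100", "20240301"),
                                     _mkrec("1002", "100", "20240301")])
        out = faerspv.deduplicate(store)
        assert [r.primaryid for r in out] == ["1003"]

    def test_dated_version_beats_undated(self):
        store = ReportStore(reports=[_mkrec("1009", "100", None),
                                     _mkrec("1002", "100", "20100101")])
        out = faerspv.deduplicate(store)
        assert [r.primaryid for r in out] == ["1002"]

    def test_numeric_primaryid_comparison(self):
        # lexicographically "9" > "1000" but numerically 1000 > 9
        store = ReportStore(reports=[_mkrec("9", "100", "20240101"),
                                     _mkrec("1000", "100", "20240101")])
        out = faerspv.deduplicate(store)
        assert [r.primaryid for r in out] == ["1000"]

    def test_idempotent_on_unique_store(self):
        store = ReportStore(reports=[_mkrec("1", "a", "20240101"),
                                     _mkrec("2", "b", "20240101")])
        once = faerspv.deduplicate(store)
        twice = faerspv.deduplicate(once)
        assert [r.primaryid for r in once] == [r.primaryid for r in twice]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_order_invariance(self, seed):
        """Permuting input rows never changes the surviving set."""
        rng = random.Random(seed)
        reports = [
            _mkrec(str(rng.randrange(1, 500)), str(rng.randrange(1, 30)),
                   rng.choice([None, "20230101", "20240101", "20250101"]))
            for _ in range(40)
        ]
        # distinct primaryids within a case so survivors are well-defined
        seen = {}
        reports = [r for r in reports
                   if seen.setdefault((r.caseid, r.primaryid), r) is r]
        base = faerspv.deduplicate(ReportStore(reports=list(reports)))
        rng.shuffle(reports)
        perm = faerspv.deduplicate(ReportStore(reports=reports))
        assert [r.primaryid for r in base] == [r.primaryid for r in perm]
        cases = [r.caseid for r in base]
        assert len(cases) == len(set(cases))


class TestRoundTrip:
    def test_store_round_trip_identity(self, tiny_store, tmp_path):
        faerspv.write_store(tiny_store, tmp_path / "store")
        back = faerspv.load_store(tmp_path / "store")
        assert len(back) == len(tiny_store)
        for a, b in zip(tiny_store, back):
            assert a == b
        assert back.provenance == tiny_store.provenance

    def test_empty_store_round_trip(self, tmp_path):
        empty = ReportStore()
        faerspv.write_store(empty, tmp_path / "empty")
        back = faerspv.load_store(tmp_path / "empty")
        assert len(back) == 0

    def test_missing_values_not_coerced_to_zero(self, tmp_path):
        rec = _mkrec("1", "c1", None)
        faerspv.write_store(ReportStore(reports=[rec]), tmp_path / "s")
        back = faerspv.load_store(tmp_path / "s")
        assert back.reports[0].age_years is None
        assert back.reports[0].fda_dt is None
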