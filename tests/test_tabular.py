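"""CSV parsing, scalar checks, profiling, and schema-driven validation."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairfmt.tabular import (CsvParseError, DateFailure, InferredType,
                             TableDocument, check_coordinate, check_date,
                             parse_csv, profile_columns, validate_table,
                             write_csv)


class TestParseCsv:
    def test_simple_table(self):
        doc = parse_csv("a,b\n1,2\n", "t.csv")
        assert doc.header == ["a", "b"]
        assert doc.rows == [["1", "2"]]

    def test_quoted_embedded_comma_kept_intact(self):
        doc = parse_csv('x,y\nv,"1,5"\n', "t.csv")
        assert doc.rows == [["v", "1,5"]]

    def test_ragged_row_is_a_parse_error_with_row_number(self):
        with pytest.raises(CsvParseError) as exc:
            parse_csv("a,b\n1\n", "t.csv")
        assert exc.value.row == 2

    def test_empty_file_is_a_parse_error(self):
        with pytest.raises(CsvParseError, match="empty"):
            parse_csv(b"", "t.csv")

    def test_crlf_and_bom_accepted(self):
        doc = parse_csv(b"\xef\xbb\xbfa,b\r\n1,2\r\n", "t.csv")
        assert doc.header == ["a", "b"] and doc.rows == [["1", "2"]]

    def test_latin1_fallback_recorded(self):
        doc = parse_csv("a\n\xe9\n".encode("latin-1"), "t.csv")
        assert doc.encoding == "latin-1"

    cell = st.text(
        alphabet=st.characters(blacklist_categories=("Cs",),
                               blacklist_characters="\r"),
        max_size=12)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(header=st.lists(cell.filter(lambda s: s.strip()), min_size=1,
                           max_size=4, unique=True),
           rows=st.lists(st.lists(cell, min_size=1, max_size=4), max_size=5))
    def test_write_then_parse_round_trip(self, header, rows):
        rows = [r[:len(header)] + [""] * (len(header) - len(r)) for r in rows]
        doc = TableDocument("rt.csv", header, rows)
        again = parse_csv(write_csv(doc), "rt.csv")
        assert again.header == doc.header and again.rows == doc.rows


class TestScalarChecks:
    @pytest.mark.parametrize("cell,expected", [
        ("2021-03-05", date(2021, 3, 5)),
        ("2021-12-31", date(2021, 12, 31)),
        ("2020-02-29", date(2020, 2, 29)),  # leap day
        ("03/05/2021", DateFailure.BAD_PATTERN),
        ("2021-3-05", DateFailure.BAD_PATTERN),  # zero padding required
        ("2021-02-30", DateFailure.BAD_CALENDAR_DATE),
        ("2021-13-01", DateFailure.BAD_CALENDAR_DATE),
        ("", DateFailure.BAD_PATTERN),
    ])
    def test_date_accepts_exactly_padded_iso_calendar_dates(self, cell,
                                                            expected):
        assert check_date(cell) == expected

    @pytest.mark.parametrize("value,axis,ok", [
        (90, "latitude", True), (-90, "latitude", True),
        (90.0001, "latitude", False), (-90.0001, "latitude", False),
        (180, "longitude", True), (-180, "longitude", True),
        (180.0001, "longitude", False), (0, "latitude", True),
    ])
    def test_coordinate_bounds_are_closed(self, value, axis, ok):
        assert check_coordinate(value, axis) is ok


class TestProfileColumns:
    def _doc(self, *cols):
        header = [f"c{i}" for i in range(len(cols))]
        rows = [list(r) for r in zip(*cols)]
        return TableDocument("p.csv", header, rows)

    def test_missing_sentinel_does_not_influence_type(self):
        doc = self._doc(["1.2", "-9999", "3.4"])
        p = profile_columns(doc, missing_codes=["-9999"])[0]
        assert p.inferred_type is InferredType.DECIMAL
        assert not p.mixed_type and p.missing_count == 1

    def test_text_among_numbers_is_mixed(self):
        p = profile_columns(self._doc(["1.2", "abc", "3.4"]))[0]
        assert p.mixed_type

    def test_integers_widen_to_decimal_without_mixing(self):
        p = profile_columns(self._doc(["1", "2.5", "3"]))[0]
        assert p.inferred_type is InferredType.DECIMAL and not p.mixed_type

    def test_all_empty_column(self):
        p = profile_columns(self._doc(["", "", ""]))[0]
        assert p.inferred_type is InferredType.EMPTY and p.missing_count == 3


class TestValidateTable:
    def test_missing_required_column_single_error(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv", ["location_id", "latitude"],
                            [["L1", "37.9"]])
        report = validate_table(doc, schema)
        errors = [i for i in report.issues if i.severity.value == "error"]
        assert [i.code for i in errors] == ["REQ-MISSING"]
        assert errors[0].location.column == "longitude"

    def test_out_of_bounds_latitude_flagged_at_cell(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv",
                            ["location_id", "latitude", "longitude"],
                            [["L1", "95", "-122.0"]])
        report = validate_table(doc, schema)
        (iss,) = report.by_code("COORD-RANGE")
        assert iss.location.row == 2 and iss.location.column == "latitude"

    def test_extra_columns_are_info_never_error(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv",
                            ["location_id", "latitude", "longitude", "color"],
                            [["L1", "37.9", "-122.0", "teal"]])
        report = validate_table(doc, schema)
        (iss,) = report.by_code("EXTRA-COLUMN")
        assert iss.severity.value == "info" and report.passed

    def test_case_insensitive_header_match_warns_with_canonical_name(
            self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv",
                            ["Location_ID", "latitude", "longitude"],
                            [["L1", "37.9", "-122.0"]])
        report = validate_table(doc, schema)
        assert report.by_code("HEADER-CASE")
        assert not report.by_code("REQ-MISSING")

    def test_missing_codes_never_raise_type_errors(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv",
                            ["location_id", "latitude", "longitude",
                             "elevation_m"],
                            [["L1", "37.9", "-122.0", "-9999"],
                             ["L2", "37.8", "-122.1", "N/A"]])
        report = validate_table(doc, schema)
        assert report.passed and not report.by_code("TYPE-MISMATCH")

    def test_sentinel_in_date_column_warns(self, registry):
        schema = registry.get("sample_metadata")
        doc = TableDocument("s.csv",
                            ["sample_id", "sample_name", "collection_date"],
                            [["S1", "core", "-9999"]])
        report = validate_table(doc, schema)
        assert report.by_code("DATE-MISSING-CODE") and report.passed

    def test_issues_sorted_by_file_row_column_code(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv",
                            ["location_id", "latitude", "longitude"],
                            [["L1", "95", "181"], ["L2", "x", "0"]])
        report = validate_table(doc, schema)
        keys = [i.sort_key() for i in report.sorted_issues()]
        assert keys == sorted(keys)

    def test_validation_is_deterministic(self, registry):
        schema = registry.get("csv_guidelines")
        doc = TableDocument("d.csv", ["a", "b"],
                            [["1", "x"], ["2.5", "y"], ["oops", "3"]])
        r1 = validate_table(doc, schema).to_json()
        r2 = validate_table(doc, schema).to_json()
        assert r1 == r2

    def test_summary_counts_match_issue_recount(self, registry):
        schema = registry.get("location_metadata")
        doc = TableDocument("loc.csv", ["location_id", "latitude"],
                            [["L1", "95"]])
        report = validate_table(doc, schema)
        s = report.summary
        assert sum(s.values()) == len(report.issues)
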