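"""Dataset metadata validation, JSON-LD export, FLMD parsing, IGSN, and
the model-archiving checklist."""

import pytest

from fairfmt.metadata import (ChecklistItem, Creator, DatasetMetadata,
                              ExportRefusedError, ModelArchiveChecklist,
                              SpatialPoint, evaluate_model_checklist,
                              export_dataset_metadata_jsonld,
                              import_dataset_metadata_jsonld, parse_flmd,
                              validate_dataset_metadata, validate_igsn)
from fairfmt.tabular import TableDocument


def full_metadata(**overrides):
    md = DatasetMetadata(
        title="Stream chemistry and sensor data from a montane watershed",
        abstract=("Water chemistry grab samples and sonde time series "
                  "collected to characterise baseflow and storm response "
                  "in a small montane catchment."),
        creators=[Creator("Ana Researcher", "State University"),
                  Creator("Ben Analyst")],
        keywords=["streams", "chemistry"],
        temporal_coverage=("2021-04-01", "2021-09-30"),
        spatial_coverage=[SpatialPoint(37.87, -122.27, "weir")],
        funding="Synthetic Science Foundation",
        related_identifiers=["doi:10.0000/related"],
    )
    for k, v in overrides.items():
        setattr(md, k, v)
    return md


class TestDatasetMetadata:
    def test_valid_metadata_passes_clean(self):
        assert validate_dataset_metadata(full_metadata()).issues == []

    def test_missing_title_is_req_missing_error(self):
        report = validate_dataset_metadata(full_metadata(title=""))
        (iss,) = report.by_code("REQ-MISSING")
        assert iss.location.column == "title" and not report.passed

    def test_short_abstract_warns_len_short(self):
        report = validate_dataset_metadata(
            full_metadata(abstract="Too short."))
        (iss,) = report.by_code("LEN-SHORT")
        assert iss.location.column == "abstract" and report.passed

    def test_interior_coordinates_raise_no_issue(self):
        report = validate_dataset_metadata(full_metadata(
            spatial_coverage=[SpatialPoint(37.87, -122.27)]))
        assert not report.by_code("COORD-RANGE")

    def test_out_of_bounds_spatial_point_errors(self):
        report = validate_dataset_metadata(full_metadata(
            spatial_coverage=[SpatialPoint(95.0, 0.0)]))
        assert report.by_code("COORD-RANGE")

    def test_reversed_temporal_coverage_errors(self):
        report = validate_dataset_metadata(full_metadata(
            temporal_coverage=("2021-09-30", "2021-04-01")))
        assert report.by_code("TEMPORAL-ORDER")

    def test_no_creator_is_req_missing(self):
        report = validate_dataset_metadata(full_metadata(creators=[]))
        assert any(i.location.column == "creator_name"
                   for i in report.by_code("REQ-MISSING"))


class TestJsonLd:
    def test_title_maps_to_schema_org_name(self):
        doc = export_dataset_metadata_jsonld(full_metadata())
        assert doc["@type"] == "Dataset"
        assert doc["name"] == full_metadata().title

    def test_round_trip_identity_on_populated_fields(self):
        md = full_metadata()
        assert import_dataset_metadata_jsonld(
            export_dataset_metadata_jsonld(md)) == md

    def test_creator_list_order_preserved(self):
        doc = export_dataset_metadata_jsonld(full_metadata())
        assert [c["name"] for c in doc["creator"]] == ["Ana Researcher",
                                                       "Ben Analyst"]

    def test_export_refused_when_presence_errors(self):
        with pytest.raises(ExportRefusedError) as exc:
            export_dataset_metadata_jsonld(full_metadata(title=""))
        assert exc.value.report.by_code("REQ-MISSING")

    def test_export_key_order_deterministic(self):
        import json
        a = json.dumps(export_dataset_metadata_jsonld(full_metadata()))
        b = json.dumps(export_dataset_metadata_jsonld(full_metadata()))
        assert a == b


FLMD_HEADER = ["file_name", "file_description", "file_format",
               "column_or_row_name_position", "missing_value_codes", "notes"]


class TestFlmd:
    def _doc(self, rows):
        return TableDocument("flmd.csv", FLMD_HEADER, rows)

    def test_three_rows_give_three_records(self, registry):
        doc = self._doc([["a.csv", "d", "csv", "1", "", ""],
                         ["b.csv", "d", "csv", "1", "-9999;N/A", ""],
                         ["c.json", "d", "json", "", "", ""]])
        records, report = parse_flmd(doc, registry)
        assert len(records) == 3 and report.passed
        assert records[1].missing_value_codes == ("-9999", "N/A")

    def test_duplicate_file_name_is_dup_file_error(self, registry):
        doc = self._doc([["a.csv", "d", "csv", "1", "", ""],
                         ["a.csv", "d2", "csv", "1", "", ""]])
        _, report = parse_flmd(doc, registry)
        (iss,) = report.by_code("DUP-FILE")
        assert iss.location.row == 3

    def test_schema_failure_yields_no_records(self, registry):
        doc = TableDocument("flmd.csv", ["file_name"], [["a.csv"]])
        records, report = parse_flmd(doc, registry)
        assert records == [] and not report.passed


class TestIgsn:
    @pytest.mark.parametrize("identifier,ok", [
        ("IGSN:IEXYZ0001", True),
        ("IEXYZ0001", True),          # prefix optional
        ("IGSN:IE123", False),        # namespace must be letters, code >= 4
        ("IGSN:X1", False),
        ("", False),
        ("IGSN:1EXYZ0001", False),    # namespace must start with letters
        ("IGSN:IEXYZ 0001", False),   # no whitespace
    ])
    def test_syntactic_acceptance(self, identifier, ok):
        assert validate_igsn(identifier).ok is ok

    def test_empty_reason_token(self):
        assert validate_igsn("").reason == "empty"
        assert validate_igsn("!!").reason == "bad_syntax"

    def test_lowercase_passes_with_case_warning(self):
        res = validate_igsn("igsn:iexyz0001")
        assert res.ok and res.case_warning
        assert res.normalized == "IGSN:IEXYZ0001"


class TestModelChecklist:
    def _cl(self, statuses):
        return ModelArchiveChecklist(
            [ChecklistItem(item, status) for item, status in statuses])

    def test_all_present_yields_zero_issues(self):
        cl = self._cl([("outputs", "present"), ("configuration", "present")])
        assert evaluate_model_checklist(cl).issues == []

    def test_absent_outputs_warns_with_guidance(self):
        cl = self._cl([("outputs", "absent")])
        (iss,) = evaluate_model_checklist(cl).issues
        assert iss.code == "MODEL-ITEM-ABSENT"
        assert "outputs" in iss.message

    def test_not_applicable_is_silent_and_never_fails_bundle(self):
        cl = self._cl([("inputs_forcings", "not_applicable"),
                       ("outputs", "absent")])
        report = evaluate_model_checklist(cl)
        assert len(report.issues) == 1
        assert report.passed  # advisory only: warnings never fail
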