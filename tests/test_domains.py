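"""Domain-format rules: amplicon counts and sequences, instrument
translation, time-series ordering, chemistry below-detection handling,
and series summaries."""

import random

import pytest

from fairfmt.domains import (UnknownFormatError, attach_sequences_from_fasta,
                             summarize_series, translate_instrument_output,
                             validate_amplicon_metadata, validate_domain_table)
from fairfmt.tabular import TableDocument, read_csv, validate_table


def amplicon_doc(rows):
    return TableDocument("amp.csv",
                         ["feature_id", "representative_sequence", "samp_01",
                          "samp_02"], rows)


class TestAmplicon:
    def test_negative_count_is_neg_count_error(self, registry):
        doc = amplicon_doc([["ASV_1", "ACGT", "-3", "5"]])
        report = validate_domain_table(doc, "amplicon_abundance", registry)
        (iss,) = report.by_code("NEG-COUNT")
        assert iss.location.column == "samp_01" and iss.location.row == 2

    def test_noninteger_count_flagged(self, registry):
        doc = amplicon_doc([["ASV_1", "ACGT", "2.5", "5"]])
        report = validate_domain_table(doc, "amplicon_abundance", registry)
        assert report.by_code("COUNT-TYPE")

    def test_duplicate_feature_id_errors(self, registry):
        doc = amplicon_doc([["ASV_1", "ACGT", "1", "2"],
                            ["ASV_1", "ACGG", "3", "4"]])
        report = validate_domain_table(doc, "amplicon_abundance", registry)
        (iss,) = report.by_code("DUP-FEATURE")
        assert iss.location.row == 3

    def test_iupac_ambiguity_warns_non_iupac_errors(self, registry):
        doc = amplicon_doc([["ASV_1", "ACGR", "1", "2"],
                            ["ASV_2", "ACGZ", "1", "2"]])
        report = validate_domain_table(doc, "amplicon_abundance", registry)
        assert len(report.by_code("SEQ-IUPAC")) == 1
        assert len(report.by_code("SEQ-INVALID")) == 1

    def test_count_validation_equals_brute_force_scan(self, registry):
        """Oracle equivalence: issues found by the validator match a
        cell-by-cell scan on randomized small tables."""
        rng = random.Random(7)
        for _ in(range(50)):
            rows = []
            expected = set()
            for i in range(rng.randrange(1, 6)):
                cells = []
                for col in ("samp_01", "samp_02"):
                    r = rng.random()
                    if r < 0.15:
                        cells.append(str(-rng.randrange(1, 9)))
                    elif r < 0.25:
                        cells.append("x")
                    else:
                        cells.append(str(rng.randrange(0, 50)))
                rows.append([f"ASV_{i}", "ACGT"] + cells)
            for i, row in enumerate(rows):  # brute-force oracle
                for j, col in enumerate(("samp_01", "samp_02"), start=2):
                    cell = row[j]
                    try:
                        if int(cell) < 0:
                            expected.add(("NEG-COUNT", i + 2, col))
                    except ValueError:
                        expected.add(("COUNT-TYPE", i + 2, col))
            report = validate_domain_table(amplicon_doc(rows),
                                           "amplicon_abundance", registry)
            got = {(i.code, i.location.row, i.location.column)
                   for i in report.issues
                   if i.code in ("NEG-COUNT", "COUNT-TYPE")}
            assert got == expected

    def test_sequences_attachable_from_fasta(self, tmp_path, registry):
        fasta = tmp_path / "reps.fasta"
        fasta.write_text(">ASV_1\nACGTACGT\n>ASV_2\nTTGGCCAA\n")
        doc = TableDocument("amp.csv", ["feature_id", "samp_01"],
                            [["ASV_1", "3"], ["ASV_2", "0"], ["ASV_9", "1"]])
        out, report = attach_sequences_from_fasta(doc, fasta)
        assert out.column("representative_sequence")[:2] == ["ACGTACGT",
                                                             "TTGGCCAA"]
        (miss,) = report.by_code("REF-UNRESOLVED")
        assert miss.location.row == 4

    def test_methods_file_requires_both_metadata_blocks(self):
        doc = TableDocument("m.csv", ["section", "attribute", "value"],
                            [["sequencing", "target_gene", "16S"]])
        report = validate_amplicon_metadata(doc)
        assert any("bioinformatics" in i.message
                   for i in report.by_code("REQ-MISSING"))


class TestChemistry:
    def _doc(self, rows):
        return TableDocument(
            "chem.csv",
            ["sample_id", "igsn", "analyte", "value", "unit", "matrix"],
            rows)

    def test_embedded_less_than_rejected_with_fixit(self, registry):
        doc = self._doc([["S1", "", "nitrate", "<0.5", "mg/L", "water"]])
        report = validate_domain_table(doc, "water_soil_chemistry", registry)
        (iss,) = report.by_code("LT-EMBEDDED")
        assert "below_detection_flag" in iss.message

    def test_novel_analyte_warns_never_errors(self, registry):
        doc = self._doc([["S1", "", "unobtainium", "1.0", "mg/L", "water"]])
        report = validate_domain_table(doc, "water_soil_chemistry", registry)
        assert report.by_code("ANALYTE-UNKNOWN") and report.passed

    def test_optional_igsn_validated_in_place(self, registry):
        doc = self._doc([["S1", "IGSN:IEXYZ0001", "nitrate", "1.0", "mg/L",
                          "water"],
                         ["S2", "IGSN:X1", "nitrate", "1.0", "mg/L", "water"]])
        report = validate_domain_table(doc, "water_soil_chemistry", registry)
        (iss,) = report.by_code("IGSN-SYNTAX")
        assert iss.location.row == 3


class TestTimeSeries:
    def _hydro(self, stamps):
        return TableDocument(
            "hydro.csv", ["datetime", "site_id", "water_level"],
            [[t, "SITE-1", "1.0"] for t in stamps])

    def test_non_monotonic_timestamps_warn_not_error(self, registry):
        doc = self._hydro(["2021-01-01T00:00:00+00:00",
                           "2021-01-01T01:00:00+00:00",
                           "2021-01-01T00:30:00+00:00"])
        report = validate_domain_table(doc, "hydrologic_monitoring", registry)
        (iss,) = report.by_code("TIME-ORDER")
        assert iss.severity.value == "warning" and report.passed

    def test_duplicate_timestamp_is_error(self, registry):
        doc = self._hydro(["2021-01-01T00:00:00+00:00",
                           "2021-01-01T00:00:00+00:00"])
        report = validate_domain_table(doc, "hydrologic_monitoring", registry)
        assert report.by_code("TIME-DUP") and not report.passed

    def test_soil_respiration_repeats_timestamp_across_gases(self, registry):
        doc = TableDocument(
            "resp.csv",
            ["timestamp", "chamber_id", "flux", "gas_species"],
            [["2021-06-01T08:00:00+00:00", "CH-1", "2.5", "CO2"],
             ["2021-06-01T08:00:00+00:00", "CH-1", "0.1", "CH4"]])
        report = validate_domain_table(doc, "soil_respiration", registry)
        assert report.passed and not report.by_code("TIME-DUP")


class TestInstrumentTranslation:
    def test_already_harmonized_header_is_identity(self):
        doc = TableDocument("g.csv", ["A", "gsw", "Ci"],
                            [["12.0", "0.2", "250"]])
        out, report = translate_instrument_output(doc, "li6800")
        assert out.header == doc.header and out.rows == doc.rows

    def test_instrument_columns_renamed_per_translation_table(self):
        doc = TableDocument("g.csv", ["Photo", "Cond", "PARi"],
                            [["12.0", "0.2", "1500"]])
        out, _ = translate_instrument_output(doc, "li6400")
        assert out.header == ["A", "gsw", "Qin"]

    def test_unmapped_column_retained_and_reported(self):
        doc = TableDocument("g.csv", ["Photo", "obs_note"], [["12.0", "ok"]])
        out, report = translate_instrument_output(doc, "li6400")
        assert "obs_note" in out.header
        assert any(i.location.column == "obs_note"
                   for i in report.by_code("MAP-UNMAPPED"))

    def test_unknown_instrument_error_lists_known(self):
        doc = TableDocument("g.csv", ["Photo"], [["12.0"]])
        with pytest.raises(UnknownFormatError, match="li6400"):
            translate_instrument_output(doc, "tricorder")

    def test_translation_idempotent_with_unit_conversion(self):
        doc = TableDocument("g.csv", ["An", "gs"], [["10.0", "150"]])
        once, _ = translate_instrument_output(doc, "ciras2")
        twice, _ = translate_instrument_output(once, "ciras2")
        assert float(once.rows[0][1]) == pytest.approx(0.15)
        assert twice.header == once.header and twice.rows == once.rows


class TestDomainSuperset:
    def test_domain_validation_contains_base_csv_issues(self, registry):
        """Any issue the base CSV schema raises is also raised under the
        domain schema."""
        doc = TableDocument(
            "hydro.csv", ["datetime", "site_id", "pH", "junk"],
            [["2021-01-01T00:00:00+00:00", "S1", "20.0", "1"],
             ["2021-01-01T01:00:00+00:00", "S1", "x", "abc"]])
        base = validate_table(doc, registry.get("csv_guidelines"))
        domain = validate_domain_table(doc, "hydrologic_monitoring", registry)
        base_sigs = {i.signature() for i in base.issues}
        domain_sigs = {i.signature() for i in domain.issues}
        # the base schema types nothing, so its findings are the
        # column-level mixed-type ones; all must survive under the domain
        # schema for columns the domain schema leaves untyped
        for sig in base_sigs:
            if sig[3] in ("junk",):
                assert sig in domain_sigs


class TestSummaries:
    def test_sentinel_excluded_from_extremes(self, registry):
        doc = TableDocument("hydro.csv", ["datetime", "water_level"],
                            [["2021-01-01T00:00:00+00:00", "1"],
                             ["2021-01-01T01:00:00+00:00", "-9999"],
                             ["2021-01-01T02:00:00+00:00", "3"]])
        s = summarize_series(doc, "hydrologic_monitoring")
        assert s["water_level"] == {"n": 3, "n_missing": 1, "min": 1.0,
                                    "max": 3.0, "start": None, "end": None}
        assert s["datetime"]["start"] == "2021-01-01T00:00:00+00:00"
        assert s["datetime"]["end"] == "2021-01-01T02:00:00+00:00"

    def test_all_missing_series_gives_null_summary(self, registry):
        doc = TableDocument("hydro.csv", ["water_level"],
                            [["-9999"], [""]])
        s = summarize_series(doc, "hydrologic_monitoring")
        assert s["water_level"]["min"] is None
        assert s["water_level"]["n_missing"] == 2

    def test_fixture_summary_matches_generator_range(self, make_bundle):
        bundle = make_bundle(formats=["hydrologic_monitoring"], seed=6)
        doc = read_csv(bundle.path("hydrologic_monitoring.csv"))
        s = summarize_series(doc, "hydrologic_monitoring")
        assert 0.2 <= s["water_level"]["min"] <= s["water_level"]["max"] <= 3.5
        assert 0 <= s["pH"]["min"] and s["pH"]["max"] <= 14
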