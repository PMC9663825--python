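"""Rules specific to the five domain reporting formats.

Each domain table first passes through the generic schema-driven CSV
validation, then through the format's own invariants: non-negative
integer counts and IUPAC sequences for amplicon tables, instrument
translation for leaf gas exchange, timestamp ordering for the time
series formats, and below-detection/analyte handling for water and
soil chemistry.  Domain validation is therefore always a superset of
the base CSV validation.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .crosswalk import CrosswalkTable, load_packaged_crosswalk, translate_headers
from .issues import ValidationReport, issue
from .metadata import looks_like_igsn, validate_igsn
from .schema import SchemaRegistry, load_registry
from .tabular import (DEFAULT_MISSING_CODES, TableDocument, is_decimal,
                      is_integer, summarize_columns, validate_table)

DOMAIN_FORMAT_IDS = ("amplicon_abundance", "leaf_gas_exchange",
                     "soil_respiration", "water_soil_chemistry",
                     "hydrologic_monitoring")

#: Strict DNA alphabet and the wider IUPAC ambiguity set.
DNA_STRICT = set("ACGTN")
DNA_IUPAC = set("ACGTNURYSWKMBDHV")

#: Packaged analyte vocabulary for water/soil chemistry.  Deliberately
#: extensible: unknown analytes warn and are collected as suggestions.
ANALYTE_VOCABULARY = frozenset({
    "nitrate", "nitrite", "ammonium", "phosphate", "sulfate", "chloride",
    "fluoride", "bromide", "calcium", "magnesium", "sodium", "potassium",
    "iron", "manganese", "aluminum", "zinc", "copper", "arsenic", "lead",
    "dissolved_organic_carbon", "total_organic_carbon", "total_nitrogen",
    "total_phosphorus", "ph", "alkalinity", "silica",
})

#: Two-block methods file accompanying an amplicon table.
AMPLICON_METADATA_SECTIONS = ("sequencing", "bioinformatics")


class UnknownFormatError(KeyError):
    pass


def _require_domain(format_id: str) -> None:
    if format_id not in DOMAIN_FORMAT_IDS:
        raise UnknownFormatError(
            f"{format_id!r} is not a domain format; expected one of "
            f"{', '.join(DOMAIN_FORMAT_IDS)}")


def validate_domain_table(doc: TableDocument, format_id: str,
                          registry: Optional[SchemaRegistry] = None,
                          missing_codes: Optional[Sequence[str]] = None
                          ) -> ValidationReport:
    """Validate a table under a domain schema plus its format rules."""
    _require_domain(format_id)
    if registry is None:
        registry = load_registry()
    schema = registry.get(format_id)
    report = validate_table(doc, schema, missing_codes=missing_codes)
    codes = set(missing_codes or DEFAULT_MISSING_CODES) | {""}
    if format_id == "amplicon_abundance":
        _check_amplicon(doc, report, codes)
    elif format_id == "water_soil_chemistry":
        _check_water_chem(doc, report, codes)
    elif format_id == "hydrologic_monitoring":
        _check_time_series(doc, report, "datetime", series_key="site_id",
                           duplicates_error=True)
    elif format_id == "soil_respiration":
        _check_time_series(doc, report, "timestamp", series_key="chamber_id",
                           duplicates_error=False)
    return report


# ---------------------------------------------------------------------------
# amplicon abundance
# ---------------------------------------------------------------------------

def _check_amplicon(doc: TableDocument, report: ValidationReport,
                    missing: set[str]) -> None:
    sid = "amplicon_abundance"
    reserved = {"feature_id", "representative_sequence"}
    count_cols = [c for c in doc.header if c not in reserved]
    for col in count_cols:
        j = doc.header.index(col)
        for i, row in enumerate(doc.rows, start=2):
            cell = row[j].strip()
            if cell in missing:
                continue
            if not is_integer(cell):
                report.add(issue("COUNT-TYPE", file=doc.source_name, row=i,
                                 column=col,
                                 message=f"count {cell!r} is not an integer",
                                 schema_id=sid))
            elif int(cell) < 0:
                report.add(issue("NEG-COUNT", file=doc.source_name, row=i,
                                 column=col,
                                 message=f"count {cell} is negative",
                                 schema_id=sid))
    if doc.has_column("feature_id"):
        seen: dict[str, int] = {}
        for i, cell in enumerate(doc.column("feature_id"), start=2):
            fid = cell.strip()
            if fid in seen:
                report.add(issue("DUP-FEATURE", file=doc.source_name, row=i,
                                 column="feature_id",
                                 message=f"feature_id {fid!r} already used on "
                                         f"row {seen[fid]}",
                                 schema_id=sid))
            else:
                seen[fid] = i
    if doc.has_column("representative_sequence"):
        for i, cell in enumerate(doc.column("representative_sequence"), start=2):
            seq = cell.strip().upper()
            if not seq:
                continue
            letters = set(seq)
            if not letters <= DNA_IUPAC:
                bad = "".join(sorted(letters - DNA_IUPAC))
                report.add(issue("SEQ-INVALID", file=doc.source_name, row=i,
                                 column="representative_sequence",
                                 message=f"non-IUPAC character(s) {bad!r} in "
                                         f"sequence",
                                 schema_id=sid))
            elif not letters <= DNA_STRICT:
                amb = "".join(sorted(letters - DNA_STRICT))
                report.add(issue("SEQ-IUPAC", file=doc.source_name, row=i,
                                 column="representative_sequence",
                                 message=f"ambiguity code(s) {amb!r} beyond "
                                         f"ACGTN",
                                 schema_id=sid))


def attach_sequences_from_fasta(doc: TableDocument, fasta_path
                                ) -> tuple[TableDocument, ValidationReport]:
    """Add a representative_sequence column from a FASTA file keyed by
    feature_id, for tables that reference sequences externally."""
    report = ValidationReport(files_checked=[doc.source_name,
                                             Path(fasta_path).name])
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = doc.copy()
    if not out.has_column("representative_sequence"):
        out.header.append("representative_sequence")
        for row in out.rows:
            row.append("")
    j = out.header.index("representative_sequence")
    fid_j = out.header.index("feature_id")
    for i, row in enumerate(out.rows, start=2):
        fid = row[fid_j].strip()
        if fid in seqs:
            row[j] = seqs[fid]
        else:
            report.add(issue("REF-UNRESOLVED", file=doc.source_name, row=i,
                             column="feature_id",
                             message=f"feature_id {fid!r} has no record in "
                                     f"{Path(fasta_path).name}",
                             schema_id="amplicon_abundance"))
    return out, report


def validate_amplicon_metadata(doc: TableDocument) -> ValidationReport:
    """Check the two-block amplicon methods file: a (section, attribute,
    value) table that must distinguish sequencing metadata from
    bioinformatic processing metadata, with both blocks present."""
    report = ValidationReport(files_checked=[doc.source_name],
                              schemas_applied=["amplicon_abundance"])
    required = {"section", "attribute", "value"}
    missing_cols = sorted(required - set(doc.header))
    for col in missing_cols:
        report.add(issue("REQ-MISSING", file=doc.source_name, row=1, column=col,
                         message=f"required column {col!r} is missing",
                         schema_id="amplicon_abundance"))
    if missing_cols:
        return report
    sections = {r[doc.header.index("section")].strip() for r in doc.rows}
    for i, row in enumerate(doc.rows, start=2):
        sec = row[doc.header.index("section")].strip()
        if sec not in AMPLICON_METADATA_SECTIONS:
            report.add(issue("VOCAB-UNKNOWN", file=doc.source_name, row=i,
                             column="section",
                             message=f"section {sec!r} must be one of "
                                     f"{AMPLICON_METADATA_SECTIONS}",
                             schema_id="amplicon_abundance"))
    for sec in AMPLICON_METADATA_SECTIONS:
        if sec not in sections:
            report.add(issue("REQ-MISSING", file=doc.source_name, row=1,
                             column=f"section:{sec}",
                             message=f"metadata block {sec!r} is missing; both "
                                     f"sequencing and bioinformatics blocks are "
                                     f"required",
                             schema_id="amplicon_abundance"))
    return report


# ---------------------------------------------------------------------------
# water / soil chemistry
# ---------------------------------------------------------------------------

def _check_water_chem(doc: TableDocument, report: ValidationReport,
                      missing: set[str]) -> None:
    sid = "water_soil_chemistry"
    if doc.has_column("value"):
        j = doc.header.index("value")
        for i, row in enumerate(doc.rows, start=2):
            cell = row[j].strip()
            if cell in missing:
                continue
            if cell.startswith("<"):
                report.add(issue(
                    "LT-EMBEDDED", file=doc.source_name, row=i, column="value",
                    message=f"{cell!r}: report below-detection results with "
                            f"below_detection_flag=TRUE and the limit in "
                            f"detection_limit, not '<' in the value",
                    schema_id=sid))
            elif not is_decimal(cell):
                report.add(issue("VALUE-TYPE", file=doc.source_name, row=i,
                                 column="value",
                                 message=f"value {cell!r} is not numeric or a "
                                         f"missing code",
                                 schema_id=sid))
    if doc.has_column("analyte"):
        j = doc.header.index("analyte")
        for i, row in enumerate(doc.rows, start=2):
            cell = row[j].strip()
            if cell and cell not in missing \
                    and cell.lower() not in ANALYTE_VOCABULARY:
                report.add(issue("ANALYTE-UNKNOWN", file=doc.source_name,
                                 row=i, column="analyte",
                                 message=f"analyte {cell!r} is not in the "
                                         f"packaged vocabulary (novel analytes "
                                         f"are allowed; consider proposing it)",
                                 schema_id=sid))
    if doc.has_column("igsn"):
        j = doc.header.index("igsn")
        for i, row in enumerate(doc.rows, start=2):
            cell = row[j].strip()
            if not cell or cell in missing:
                continue
            res = validate_igsn(cell)
            if not res.ok:
                report.add(issue("IGSN-SYNTAX", file=doc.source_name, row=i,
                                 column="igsn",
                                 message=f"{cell!r} is not a valid IGSN "
                                         f"({res.reason})",
                                 schema_id=sid))
            elif res.case_warning:
                report.add(issue("IGSN-CASE", file=doc.source_name, row=i,
                                 column="igsn",
                                 message=f"{cell!r}: canonical form is "
                                         f"{res.normalized!r}",
                                 schema_id=sid))


def collect_novel_analytes(doc: TableDocument) -> list[str]:
    """Suggestions list: analytes seen in a table but absent from the
    packaged vocabulary."""
    if not doc.has_column("analyte"):
        return []
    return sorted({c.strip() for c in doc.column("analyte")
                   if c.strip() and c.strip().lower() not in ANALYTE_VOCABULARY})


# ---------------------------------------------------------------------------
# time series (soil respiration, hydrologic monitoring)
# ---------------------------------------------------------------------------

def _check_time_series(doc: TableDocument, report: ValidationReport,
                       time_col: str, series_key: str,
                       duplicates_error: bool) -> None:
    """Out-of-order timestamps warn (re-deployments happen in the
    field); duplicate timestamps within a series indicate merge faults
    and error where the format says so."""
    if not doc.has_column(time_col):
        return
    sid = report.schemas_applied[0] if report.schemas_applied else ""
    j = doc.header.index(time_col)
    kj = doc.header.index(series_key) if doc.has_column(series_key) else None
    prev: dict[str, tuple[datetime, int]] = {}
    seen: dict[tuple[str, str], int] = {}
    for i, row in enumerate(doc.rows, start=2):
        cell = row[j].strip()
        if not cell:
            continue
        try:
            ts = datetime.fromisoformat(cell)
        except ValueError:
            continue  # format errors already reported by the base schema
        key = row[kj].strip() if kj is not None else ""
        if (key, cell) in seen:
            if duplicates_error:
                report.add(issue("TIME-DUP", file=doc.source_name, row=i,
                                 column=time_col,
                                 message=f"timestamp {cell!r} duplicates row "
                                         f"{seen[(key, cell)]} for series "
                                         f"{key!r}",
                                 schema_id=sid))
        else:
            seen[(key, cell)] = i
            if key in prev and ts < prev[key][0]:
                report.add(issue("TIME-ORDER", file=doc.source_name, row=i,
                                 column=time_col,
                                 message=f"timestamp {cell!r} precedes row "
                                         f"{prev[key][1]}'s timestamp for "
                                         f"series {key!r}",
                                 schema_id=sid))
        if key not in prev or ts >= prev[key][0]:
            prev[key] = (ts, i)


# ---------------------------------------------------------------------------
# instrument translation & series summaries
# ---------------------------------------------------------------------------

def known_instruments(table: Optional[CrosswalkTable] = None) -> list[str]:
    if table is None:
        table = load_packaged_crosswalk("leaf_gas_exchange")
    return table.standards()


def translate_instrument_output(doc: TableDocument, instrument: str,
                                table: Optional[CrosswalkTable] = None,
                                registry: Optional[SchemaRegistry] = None
                                ) -> tuple[TableDocument, ValidationReport]:
    """Rename instrument-native gas-exchange columns onto the harmonized
    variable names, applying declared unit conversions.

    Unmapped source columns are preserved verbatim and listed in the
    report.  Unknown instruments raise, listing the instruments the
    packaged translation table covers.  Idempotent: translating an
    already-harmonized table is the identity.
    """
    if table is None:
        table = load_packaged_crosswalk("leaf_gas_exchange")
    if instrument not in table.standards():
        raise UnknownFormatError(
            f"unknown instrument {instrument!r}; known instruments: "
            f"{', '.join(table.standards())}")
    schema = None
    if registry is not None:
        schema = registry.get("leaf_gas_exchange")
    return translate_headers(doc, table, instrument, schema=schema)


def summarize_series(doc: TableDocument, format_id: str,
                     missing_codes: Optional[Sequence[str]] = None
                     ) -> dict[str, dict]:
    """Per-variable QA summary (n, n_missing, min, max, start, end),
    with missing codes excluded from extremes."""
    _require_domain(format_id)
    return summarize_columns(doc, missing_codes or DEFAULT_MISSING_CODES)
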