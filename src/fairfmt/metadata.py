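"""Cross-domain metadata formats: dataset metadata (with JSON-LD
export), file-level metadata (FLMD), IGSN sample identifiers, and the
terrestrial model-archiving checklist."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Union

from .issues import Severity, ValidationReport, issue
from .tabular import TableDocument, check_coordinate, check_date

# Length-check defaults: warnings only, configurable.
MIN_TITLE_CHARS = 40
MIN_ABSTRACT_CHARS = 100

JSONLD_CONTEXT = "https://schema.org/"

# IGSN syntax: optional scheme prefix, 2-5 letter namespace, then at
# least 4 alphanumerics.  Syntactic check only; no resolution.
_IGSN_RE = re.compile(r"^(IGSN:)?([A-Z]{2,5})([A-Z0-9]{4,})$")


@dataclass(frozen=True)
class Creator:
    name: str
    affiliation: str = ""
    identifier: str = ""


@dataclass(frozen=True)
class SpatialPoint:
    latitude: float
    longitude: float
    description: str = ""


@dataclass
class DatasetMetadata:
    """Canonical in-memory dataset metadata, independent of whether it
    arrived as JSON or as the flat CSV template."""

    title: str = ""
    abstract: str = ""
    creators: list[Creator] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    temporal_coverage: tuple[str, str] = ("", "")
    spatial_coverage: list[SpatialPoint] = field(default_factory=list)
    funding: str = ""
    related_identifiers: list[str] = field(default_factory=list)


class MetadataParseError(ValueError):
    pass


def parse_dataset_metadata_json(text: str,
                                source_name: str = "dataset_metadata.json"
                                ) -> DatasetMetadata:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MetadataParseError(f"{source_name}: not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise MetadataParseError(f"{source_name}: expected a JSON object")
    creators = [Creator(c.get("name", ""), c.get("affiliation", ""),
                        c.get("identifier", ""))
                for c in raw.get("creators", [])]
    tc = raw.get("temporal_coverage", {}) or {}
    spatial = [SpatialPoint(float(p["latitude"]), float(p["longitude"]),
                            p.get("description", ""))
               for p in raw.get("spatial_coverage", [])]
    return DatasetMetadata(
        title=raw.get("title", ""),
        abstract=raw.get("abstract", ""),
        creators=creators,
        keywords=list(raw.get("keywords", [])),
        temporal_coverage=(tc.get("start_date", ""), tc.get("end_date", "")),
        spatial_coverage=spatial,
        funding=raw.get("funding", ""),
        related_identifiers=list(raw.get("related_identifiers", [])),
    )


def dataset_metadata_to_json(md: DatasetMetadata) -> str:
    doc = {
        "title": md.title,
        "abstract": md.abstract,
        "creators": [{"name": c.name, "affiliation": c.affiliation,
                      "identifier": c.identifier} for c in md.creators],
        "keywords": md.keywords,
        "temporal_coverage": {"start_date": md.temporal_coverage[0],
                              "end_date": md.temporal_coverage[1]},
        "spatial_coverage": [{"latitude": p.latitude, "longitude": p.longitude,
                              "description": p.description}
                             for p in md.spatial_coverage],
        "funding": md.funding,
        "related_identifiers": md.related_identifiers,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def validate_dataset_metadata(md: DatasetMetadata,
                              source_name: str = "dataset_metadata.json",
                              min_title_chars: int = MIN_TITLE_CHARS,
                              min_abstract_chars: int = MIN_ABSTRACT_CHARS,
                              ) -> ValidationReport:
    """Presence, format, and length checks on dataset metadata.

    Presence failures (no title, no abstract, no creator) are errors;
    format failures on dates/coordinates are errors; length shortfalls
    are warnings with configurable minimums.
    """
    report = ValidationReport(files_checked=[source_name],
                              schemas_applied=["dataset_metadata"])

    def req_missing(col: str) -> None:
        report.add(issue("REQ-MISSING", file=source_name, column=col,
                         message=f"required metadata field {col!r} is missing",
                         schema_id="dataset_metadata"))

    if not md.title.strip():
        req_missing("title")
    elif len(md.title.strip()) < min_title_chars:
        report.add(issue("LEN-SHORT", file=source_name, column="title",
                         message=f"title has {len(md.title.strip())} characters; "
                                 f"aim for at least {min_title_chars}",
                         schema_id="dataset_metadata"))
    if not md.abstract.strip():
        req_missing("abstract")
    elif len(md.abstract.strip()) < min_abstract_chars:
        report.add(issue("LEN-SHORT", file=source_name, column="abstract",
                         message=f"abstract has {len(md.abstract.strip())} "
                                 f"characters; aim for at least "
                                 f"{min_abstract_chars}",
                         schema_id="dataset_metadata"))
    if not any(c.name.strip() for c in md.creators):
        req_missing("creator_name")

    parsed: dict[str, Optional[date]] = {}
    for col, cell in zip(("start_date", "end_date"), md.temporal_coverage):
        parsed[col] = None
        if not cell:
            continue
        res = check_date(cell)
        if isinstance(res, date):
            parsed[col] = res
        else:
            code = ("DATE-FORMAT" if res.value == "bad_pattern"
                    else "DATE-INVALID")
            report.add(issue(code, file=source_name, column=col,
                             message=f"{cell!r} is not a valid YYYY-MM-DD date",
                             schema_id="dataset_metadata"))
    if parsed["start_date"] and parsed["end_date"] \
            and parsed["start_date"] > parsed["end_date"]:
        report.add(issue("TEMPORAL-ORDER", file=source_name, column="start_date",
                         message=f"temporal coverage starts "
                                 f"{md.temporal_coverage[0]} after it ends "
                                 f"{md.temporal_coverage[1]}",
                         schema_id="dataset_metadata"))
    for k, p in enumerate(md.spatial_coverage, start=1):
        for axis, v in (("latitude", p.latitude), ("longitude", p.longitude)):
            if not check_coordinate(v, axis):
                report.add(issue("COORD-RANGE", file=source_name,
                                 column=f"spatial_coverage[{k}].{axis}",
                                 message=f"{axis} {v} out of bounds",
                                 schema_id="dataset_metadata"))
    return report


# ---------------------------------------------------------------------------
# JSON-LD (schema.org Dataset profile)
# ---------------------------------------------------------------------------

class ExportRefusedError(ValueError):
    """Export refused because presence checks fail; carries the report."""

    def __init__(self, report: ValidationReport):
        super().__init__("dataset metadata fails presence checks; "
                         "fix errors before exporting JSON-LD")
        self.report = report


def export_dataset_metadata_jsonld(md: DatasetMetadata) -> dict:
    """Emit a schema.org ``Dataset`` JSON-LD document.

    Lossless for every populated field and refuses to export metadata
    with presence errors.  Key order is deterministic.
    """
    report = validate_dataset_metadata(md)
    if report.by_code("REQ-MISSING"):
        raise ExportRefusedError(report)
    doc: dict = {
        "@context": JSONLD_CONTEXT,
        "@type": "Dataset",
        "name": md.title,
        "description": md.abstract,
        "creator": [
            {"@type": "Person", "name": c.name,
             **({"affiliation": c.affiliation} if c.affiliation else {}),
             **({"identifier": c.identifier} if c.identifier else {})}
            for c in md.creators
        ],
    }
    if md.keywords:
        doc["keywords"] = list(md.keywords)
    start, end = md.temporal_coverage
    if start or end:
        doc["temporalCoverage"] = f"{start}/{end}"
    if md.spatial_coverage:
        doc["spatialCoverage"] = [
            {"@type": "Place",
             **({"description": p.description} if p.description else {}),
             "geo": {"@type": "GeoCoordinates", "latitude": p.latitude,
                     "longitude": p.longitude}}
            for p in md.spatial_coverage
        ]
    if md.funding:
        doc["funder"] = {"@type": "Organization", "name": md.funding}
    if md.related_identifiers:
        doc["identifier"] = list(md.related_identifiers)
    return doc


def import_dataset_metadata_jsonld(doc: dict) -> DatasetMetadata:
    """Inverse of :func:`export_dataset_metadata_jsonld` on populated
    fields: import(export(md)) == md."""
    tc = doc.get("temporalCoverage", "/")
    start, _, end = tc.partition("/") if tc else ("", "", "")
    funder = doc.get("funder", {})
    return DatasetMetadata(
        title=doc.get("name", ""),
        abstract=doc.get("description", ""),
        creators=[Creator(c.get("name", ""), c.get("affiliation", ""),
                          c.get("identifier", ""))
                  for c in doc.get("creator", [])],
        keywords=list(doc.get("keywords", [])),
        temporal_coverage=(start, end),
        spatial_coverage=[
            SpatialPoint(p["geo"]["latitude"], p["geo"]["longitude"],
                         p.get("description", ""))
            for p in doc.get("spatialCoverage", [])],
        funding=funder.get("name", "") if isinstance(funder, dict) else "",
        related_identifiers=list(doc.get("identifier", [])),
    )


# ---------------------------------------------------------------------------
# file-level metadata (FLMD)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FileLevelMetadataRecord:
    file_name: str
    description: str = ""
    file_format: str = ""
    column_or_row_name_position: Optional[int] = None
    missing_value_codes: tuple[str, ...] = ()
    notes: str = ""


def parse_flmd(doc: TableDocument, registry=None
               ) -> tuple[list[FileLevelMetadataRecord], ValidationReport]:
    """Interpret an FLMD table, validating it under its own schema first
    (the FLMD format is itself a CSV reporting format).

    Returns no records when schema validation fails with errors.
    Duplicate file_name rows are DUP-FILE errors.
    """
    from .schema import load_registry
    from .tabular import validate_table
    if registry is None:
        registry = load_registry()
    schema = registry.get("file_level_metadata")
    report = validate_table(doc, schema)
    if not report.passed:
        return [], report

    def col(row, name):
        return row[doc.header.index(name)].strip() if name in doc.header else ""

    records = []
    seen: dict[str, int] = {}
    for i, row in enumerate(doc.rows, start=2):
        fname = col(row, "file_name")
        if fname in seen:
            report.add(issue("DUP-FILE", file=doc.source_name, row=i,
                             column="file_name",
                             message=f"file_name {fname!r} already described "
                                     f"on row {seen[fname]}",
                             schema_id="file_level_metadata"))
        else:
            seen[fname] = i
        pos = col(row, "column_or_row_name_position")
        codes = tuple(c.strip() for c in
                      col(row, "missing_value_codes").split(";") if c.strip())
        records.append(FileLevelMetadataRecord(
            file_name=fname,
            description=col(row, "file_description"),
            file_format=col(row, "file_format"),
            column_or_row_name_position=int(pos) if pos else None,
            missing_value_codes=codes,
            notes=col(row, "notes"),
        ))
    return records, report


# ---------------------------------------------------------------------------
# IGSN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IgsnResult:
    ok: bool
    reason: str = ""            # "", "empty", "bad_syntax"
    normalized: str = ""
    case_warning: bool = False


def validate_igsn(identifier: str) -> IgsnResult:
    """Syntactic IGSN check (no network resolution).

    Accepts an optional ``IGSN:`` scheme prefix, a 2-5 letter namespace,
    and at least four alphanumerics.  Lowercase input passes with a
    case-normalization warning; canonical IGSNs are upper case.
    """
    s = identifier.strip()
    if not s:
        return IgsnResult(False, "empty")
    upper = s.upper()
    m = _IGSN_RE.match(upper)
    if not m:
        return IgsnResult(False, "bad_syntax")
    return IgsnResult(True, "", normalized=upper, case_warning=(s != upper))


def looks_like_igsn(identifier: str) -> bool:
    """Heuristic used by bundle checks: treat explicitly prefixed ids as
    IGSN candidates."""
    return identifier.strip().upper().startswith("IGSN:")


# ---------------------------------------------------------------------------
# model-archiving checklist
# ---------------------------------------------------------------------------

CHECKLIST_ITEMS = ("model_code_version", "inputs_forcings", "configuration",
                   "outputs", "postprocessing_scripts", "documentation")

_GUIDANCE = {
    "model_code_version": "archive or cite the exact model code revision",
    "inputs_forcings": "archive input and forcing datasets (or cite their DOIs)",
    "configuration": "archive namelists/parameter files defining the run",
    "outputs": "archive the model outputs that support the findings",
    "postprocessing_scripts": "archive scripts that turn raw output into figures",
    "documentation": "document how to reproduce the run end to end",
}


@dataclass(frozen=True)
class ChecklistItem:
    item: str
    status: str  # present | absent | not_applicable
    evidence_file: str = ""


@dataclass
class ModelArchiveChecklist:
    items: list[ChecklistItem]

    @classmethod
    def from_table(cls, doc: TableDocument) -> "ModelArchiveChecklist":
        idx = {c: doc.header.index(c) for c in ("item", "status")}
        ev = doc.header.index("evidence_file") if "evidence_file" in doc.header else None
        return cls([ChecklistItem(r[idx["item"]].strip(), r[idx["status"]].strip(),
                                  r[ev].strip() if ev is not None else "")
                    for r in doc.rows])


def evaluate_model_checklist(checklist: ModelArchiveChecklist,
                             source_name: str = "model_checklist.csv"
                             ) -> ValidationReport:
    """Advisory-only evaluation: absent components yield warnings with
    guidance; not_applicable items are silent.  Never errors, so the
    checklist cannot fail a bundle."""
    report = ValidationReport(files_checked=[source_name],
                              schemas_applied=["model_archiving"])
    for i, item in enumerate(checklist.items, start=2):
        if item.status == "absent":
            guidance = _GUIDANCE.get(item.item, "consider archiving this component")
            report.add(issue("MODEL-ITEM-ABSENT", file=source_name, row=i,
                             column="status",
                             message=f"{item.item}: marked absent — {guidance}",
                             schema_id="model_archiving"))
    return report
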