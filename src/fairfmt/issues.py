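"""Validation issue codes, severities, and report containers.

Every finding the toolkit can emit carries a stable code from the
catalogue below.  Codes never change meaning between releases; new
checks get new codes.  Severity semantics:

* ``error``   — the file violates a reporting-format rule and would not
  be machine-parseable as intended; a bundle with errors fails.
* ``warning`` — the file deviates from a recommendation or uses a
  pattern that usually indicates a mistake; bundles still pass.
* ``info``    — advisory context (e.g. columns beyond the schema, which
  the formats explicitly permit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

REPORT_SCHEMA_VERSION = "1.0"


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


_SEVERITY_ORDER = {Severity.ERROR: 0, Severity.WARNING: 1, Severity.INFO: 2}


@dataclass(frozen=True)
class IssueCode:
    """Catalogue entry for one issue code."""

    code: str
    severity: Severity
    mutable: bool  # whether the fixture generator can inject this issue
    description: str


# The published catalogue.  ``mutable`` marks codes for which
# :func:`fairfmt.fixtures.mutate_bundle` has a fault generator.
CATALOGUE: dict[str, IssueCode] = {
    c.code: c
    for c in [
        # -- header / column structure ---------------------------------
        IssueCode("REQ-MISSING", Severity.ERROR, True,
                  "A required field or column is absent."),
        IssueCode("HEADER-CASE", Severity.WARNING, False,
                  "Column name matches a schema field only after case/whitespace folding."),
        IssueCode("EXTRA-COLUMN", Severity.INFO, False,
                  "Column is not defined by the schema (permitted; formats are extensible)."),
        # -- cell-level type / format ----------------------------------
        IssueCode("TYPE-MISMATCH", Severity.ERROR, True,
                  "Cell value does not parse as the declared column type."),
        IssueCode("PATTERN-MISMATCH", Severity.ERROR, False,
                  "Cell value does not match the declared regular expression."),
        IssueCode("VOCAB-UNKNOWN", Severity.ERROR, True,
                  "Cell value is outside the controlled vocabulary."),
        IssueCode("BOUNDS-RANGE", Severity.ERROR, True,
                  "Numeric cell value lies outside the declared bounds."),
        IssueCode("COORD-RANGE", Severity.ERROR, True,
                  "Coordinate outside closed bounds (latitude +/-90, longitude +/-180)."),
        IssueCode("DATE-FORMAT", Severity.ERROR, True,
                  "Date cell is not in zero-padded YYYY-MM-DD form."),
        IssueCode("DATE-INVALID", Severity.ERROR, True,
                  "Date cell matches YYYY-MM-DD but is not a real calendar date."),
        IssueCode("DATETIME-FORMAT", Severity.ERROR, False,
                  "Datetime cell is not ISO 8601."),
        IssueCode("DATETIME-NAIVE", Severity.WARNING, False,
                  "Datetime cell lacks a UTC offset."),
        IssueCode("DATE-MISSING-CODE", Severity.WARNING, False,
                  "Numeric missing sentinel (-9999) used in a date column; leave date cells empty instead."),
        IssueCode("MIXED-TYPES", Severity.ERROR, True,
                  "Column mixes conflicting scalar types."),
        # -- dataset metadata ------------------------------------------
        IssueCode("LEN-SHORT", Severity.WARNING, True,
                  "Free-text metadata field is shorter than the recommended minimum length."),
        IssueCode("TEMPORAL-ORDER", Severity.ERROR, False,
                  "Temporal coverage start date is after the end date."),
        # -- bundle cross-file -----------------------------------------
        IssueCode("DUP-FILE", Severity.ERROR, True,
                  "Duplicate file_name rows in the file-level metadata table."),
        IssueCode("FILE-MISSING", Severity.ERROR, True,
                  "File-level metadata names a file that is not in the bundle."),
        IssueCode("FILE-UNDOCUMENTED", Severity.WARNING, True,
                  "Bundle file has no file-level metadata row."),
        IssueCode("REF-UNRESOLVED", Severity.ERROR, True,
                  "Identifier referenced in a data table is not defined in the sample/location registry."),
        # -- sample identifiers ----------------------------------------
        IssueCode("IGSN-SYNTAX", Severity.ERROR, True,
                  "Identifier does not match IGSN syntax (optional IGSN: prefix, 2-5 letter namespace, >=4 alphanumerics)."),
        IssueCode("IGSN-CASE", Severity.WARNING, False,
                  "IGSN is valid after uppercasing; canonical IGSNs are upper case."),
        # -- model archiving (advisory only) ---------------------------
        IssueCode("MODEL-ITEM-ABSENT", Severity.WARNING, False,
                  "Recommended model-archive component is marked absent."),
        # -- amplicon abundance ----------------------------------------
        IssueCode("NEG-COUNT", Severity.ERROR, True,
                  "Amplicon count is negative."),
        IssueCode("COUNT-TYPE", Severity.ERROR, False,
                  "Amplicon count is not an integer."),
        IssueCode("DUP-FEATURE", Severity.ERROR, True,
                  "Duplicate feature_id in an abundance table."),
        IssueCode("SEQ-INVALID", Severity.ERROR, True,
                  "Representative sequence contains characters outside the IUPAC DNA alphabet."),
        IssueCode("SEQ-IUPAC", Severity.WARNING, True,
                  "Representative sequence uses IUPAC ambiguity codes beyond ACGTN."),
        # -- time series -----------------------------------------------
        IssueCode("TIME-ORDER", Severity.WARNING, True,
                  "Timestamps are not monotonically non-decreasing."),
        IssueCode("TIME-DUP", Severity.ERROR, True,
                  "Duplicate timestamp for the same series."),
        # -- water/soil chemistry --------------------------------------
        IssueCode("LT-EMBEDDED", Severity.ERROR, True,
                  "Below-detection result embedded as '<value' in a numeric cell; use the "
                  "below_detection_flag and detection_limit columns instead."),
        IssueCode("VALUE-TYPE", Severity.ERROR, False,
                  "Measured value is neither numeric nor a recognised missing code."),
        IssueCode("ANALYTE-UNKNOWN", Severity.WARNING, True,
                  "Analyte name is outside the packaged vocabulary (novel analytes are allowed)."),
        # -- crosswalk translation -------------------------------------
        IssueCode("MAP-COLLISION", Severity.ERROR, False,
                  "Two source columns map onto the same harmonized name; no rename applied."),
        IssueCode("MAP-UNMAPPED", Severity.INFO, False,
                  "Column has no crosswalk entry and was preserved verbatim."),
    ]
}

MUTABLE_CODES: tuple[str, ...] = tuple(
    sorted(c.code for c in CATALOGUE.values() if c.mutable)
)


@dataclass(frozen=True)
class Location:
    """Where an issue was found.

    Row indices are 1-based and count the header as row 1, matching what
    users see in a spreadsheet.  ``row=None`` means the issue concerns
    the file (or a non-tabular document) as a whole.
    """

    file: str = ""
    row: Optional[int] = None
    column: str = ""

    def __lt__(self, other: "Location") -> bool:  # None rows sort first
        return (self.file, self.row is not None, self.row or 0, self.column) < (
            other.file, other.row is not None, other.row or 0, other.column)


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: Severity
    location: Location
    message: str
    schema_id: str = ""

    def __post_init__(self) -> None:
        if self.code not in CATALOGUE:
            raise ValueError(f"unknown issue code {self.code!r}")

    def sort_key(self):
        return (self.location.file, self.location.row is not None,
                self.location.row or 0, self.location.column, self.code)

    def signature(self) -> tuple:
        """Identity used when diffing reports (messages excluded)."""
        return (self.code, self.location.file, self.location.row,
                self.location.column)

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity.value,
            "file": self.location.file,
            "row": self.location.row,
            "column": self.location.column,
            "message": self.message,
            "schema_id": self.schema_id,
        }


def issue(code: str, *, file: str = "", row: Optional[int] = None,
          column: str = "", message: str, schema_id: str = "",
          severity: Optional[Severity] = None) -> ValidationIssue:
    """Build an issue with the catalogue's default severity for ``code``."""
    sev = severity if severity is not None else CATALOGUE[code].severity
    return ValidationIssue(code, sev, Location(file, row, column), message,
                           schema_id)


@dataclass
class ValidationReport:
    """Ordered collection of issues plus what was checked.

    Issues are kept sorted by (file, row, column, code) so reports are
    deterministic and diffable.
    """

    issues: list[ValidationIssue] = field(default_factory=list)
    files_checked: list[str] = field(default_factory=list)
    schemas_applied: list[str] = field(default_factory=list)

    def add(self, iss: ValidationIssue) -> None:
        self.issues.append(iss)

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)
        for f in other.files_checked:
            if f not in self.files_checked:
                self.files_checked.append(f)
        for s in other.schemas_applied:
            if s not in self.schemas_applied:
                self.schemas_applied.append(s)

    def sorted_issues(self) -> list[ValidationIssue]:
        return sorted(self.issues, key=lambda i: i.sort_key())

    def count(self, severity: Severity) -> int:
        return sum(1 for i in self.issues if i.severity is severity)

    @property
    def summary(self) -> dict[str, int]:
        return {s.value: self.count(s) for s in Severity}

    @property
    def passed(self) -> bool:
        """A report with zero errors is a pass."""
        return self.count(Severity.ERROR) == 0

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]

    def worst_at_or_above(self, threshold: Severity) -> bool:
        limit = _SEVERITY_ORDER[threshold]
        return any(_SEVERITY_ORDER[i.severity] <= limit for i in self.issues)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "report_version": REPORT_SCHEMA_VERSION,
            "files_checked": sorted(self.files_checked),
            "schemas_applied": sorted(self.schemas_applied),
            "summary": self.summary,
            "passed": self.passed,
            "issues": [i.to_dict() for i in self.sorted_issues()],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)

    def to_text(self) -> str:
        lines = []
        for i in self.sorted_issues():
            loc = i.location.file or "-"
            if i.location.row is not None:
                loc += f":{i.location.row}"
            if i.location.column:
                loc += f":{i.location.column}"
            lines.append(f"{i.severity.value.upper():7s} {i.code:16s} {loc}  {i.message}")
        s = self.summary
        lines.append(
            f"{len(self.issues)} issue(s): {s['error']} error(s), "
            f"{s['warning']} warning(s), {s['info']} info. "
            + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


def merge(reports: Iterable[ValidationReport]) -> ValidationReport:
    out = ValidationReport()
    for r in reports:
        out.extend(r)
    return out
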