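"""Format-agnostic CSV parsing, profiling, and schema-driven validation.

Implements the tabular-data guidelines shared by all the reporting
formats: RFC 4180 CSV dialect, zero-padded ``YYYY-MM-DD`` dates,
ISO 8601 timestamps, decimal-degree coordinates with closed bounds
(latitude within [-90, 90], longitude within [-180, 180]), the ``-9999``
numeric missing sentinel, and the no-mixed-types-in-a-column rule.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from typing import BinaryIO, Iterable, Optional, Sequence, Union

from .issues import (Severity, ValidationIssue, ValidationReport, issue)

#: Default in-band sentinel for absent numeric observations.
NUMERIC_MISSING_CODE = "-9999"
#: Default missing codes: the numeric sentinel plus text conventions.
DEFAULT_MISSING_CODES = ("", NUMERIC_MISSING_CODE, "N/A")

LATITUDE_BOUNDS = (-90.0, 90.0)
LONGITUDE_BOUNDS = (-180.0, 180.0)

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_DECIMAL_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_IDENTIFIER_RE = re.compile(r"^\S+$")


class CsvParseError(ValueError):
    """Structural CSV failure (ragged row, empty file, bad encoding)."""

    def __init__(self, message: str, source_name: str = "", row: Optional[int] = None):
        super().__init__(message)
        self.source_name = source_name
        self.row = row


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    quotechar: str = '"'
    lineterminator: str = "\n"


@dataclass
class TableDocument:
    """A parsed tabular file: header + text cells + provenance.

    Cells are kept verbatim as text; typing is a validation concern, not
    a parsing one.  Every row has exactly ``len(header)`` cells.
    """

    source_name: str
    header: list[str]
    rows: list[list[str]]
    encoding: str = "utf-8"
    dialect: Dialect = field(default_factory=Dialect)

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.header):
                raise CsvParseError(
                    f"{self.source_name}: row {i + 2} has {len(row)} cells, "
                    f"expected {len(self.header)}",
                    self.source_name, i + 2)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[str]:
        idx = self.header.index(name)
        return [r[idx] for r in self.rows]

    def has_column(self, name: str) -> bool:
        return name in self.header

    def copy(self) -> "TableDocument":
        return TableDocument(self.source_name, list(self.header),
                             [list(r) for r in self.rows], self.encoding,
                             self.dialect)


def parse_csv(stream: Union[bytes, BinaryIO, str], source_name: str = "",
              dialect_hint: Optional[Dialect] = None) -> TableDocument:
    """Parse an RFC 4180 CSV byte stream into a :class:`TableDocument`.

    Encoding defaults to UTF-8 with a latin-1 fallback; the encoding
    actually used is recorded on the document.  Ragged rows and empty
    files raise :class:`CsvParseError` rather than being silently fixed.
    """
    if isinstance(stream, str):
        data = stream.encode("utf-8")
    elif isinstance(stream, bytes):
        data = stream
    else:
        data = stream.read()
    if data.startswith(b"\xef\xbb\xbf"):  # strip a UTF-8 BOM
        data = data[3:]
    encoding = "utf-8"
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        try:
            text = data.decode("latin-1")
            encoding = "latin-1"
        except UnicodeDecodeError as exc:  # pragma: no cover - latin-1 is total
            raise CsvParseError(f"{source_name}: undecodable bytes: {exc}",
                                source_name)
    if not text.strip():
        raise CsvParseError(f"{source_name}: empty file", source_name)

    dialect = dialect_hint or Dialect()
    reader = csv.reader(io.StringIO(text, newline=""),
                        delimiter=dialect.delimiter,
                        quotechar=dialect.quotechar)
    records = [row for row in reader]
    # a trailing newline yields no empty record; interior blank lines do
    records = [r for r in records if r != []]
    header = records[0]
    rows = []
    for i, row in enumerate(records[1:], start=2):
        if len(row) != len(header):
            raise CsvParseError(
                f"{source_name}: row {i} has {len(row)} cells, expected "
                f"{len(header)}", source_name, i)
        rows.append(row)
    return TableDocument(source_name, header, rows, encoding, dialect)


def read_csv(path) -> TableDocument:
    with open(path, "rb") as fh:
        return parse_csv(fh, source_name=getattr(path, "name", str(path)).split("/")[-1])


def write_csv(doc: TableDocument, path=None) -> str:
    """Serialise a document back to RFC 4180 CSV text.

    Writing then re-parsing yields an identical document.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=doc.dialect.delimiter,
                        quotechar=doc.dialect.quotechar,
                        lineterminator=doc.dialect.lineterminator)
    writer.writerow(doc.header)
    writer.writerows(doc.rows)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding=doc.encoding, newline="") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# scalar checks
# ---------------------------------------------------------------------------

class DateFailure(str, Enum):
    BAD_PATTERN = "bad_pattern"
    BAD_CALENDAR_DATE = "bad_calendar_date"


def check_date(cell: str) -> Union[date, DateFailure]:
    """Accept exactly zero-padded ``YYYY-MM-DD`` real calendar dates.

    Anything else fails with a reason: ``bad_pattern`` for shape
    failures (slashes, missing zero padding, ...), ``bad_calendar_date``
    for well-shaped non-dates like 2021-02-30.
    """
    if not _DATE_RE.match(cell):
        return DateFailure.BAD_PATTERN
    y, m, d = (int(p) for p in cell.split("-"))
    try:
        return date(y, m, d)
    except ValueError:
        return DateFailure.BAD_CALENDAR_DATE


class DatetimeResult(str, Enum):
    AWARE = "aware"
    NAIVE = "naive"
    INVALID = "invalid"


def check_datetime(cell: str) -> DatetimeResult:
    """Classify an ISO 8601 timestamp.

    Date-only values count as (naive) timestamps; a UTC offset or ``Z``
    makes the value aware.  Naive timestamps are legal but warned about
    by the table validator.
    """
    try:
        dt = datetime.fromisoformat(cell)
    except ValueError:
        d = check_date(cell)
        return DatetimeResult.NAIVE if isinstance(d, date) else DatetimeResult.INVALID
    return (DatetimeResult.AWARE if dt.tzinfo is not None
            else DatetimeResult.NAIVE)


def check_coordinate(value: float, axis: str) -> bool:
    """Closed-interval bound check for decimal-degree coordinates."""
    if axis == "latitude":
        lo, hi = LATITUDE_BOUNDS
    elif axis == "longitude":
        lo, hi = LONGITUDE_BOUNDS
    else:
        raise ValueError(f"axis must be latitude or longitude, got {axis!r}")
    return lo <= value <= hi


def is_integer(cell: str) -> bool:
    return bool(_INT_RE.match(cell))


def is_decimal(cell: str) -> bool:
    return bool(_DECIMAL_RE.match(cell))


# ---------------------------------------------------------------------------
# column profiling
# ---------------------------------------------------------------------------

class InferredType(str, Enum):
    INTEGER = "integer"
    DECIMAL = "decimal"
    DATE = "date"
    DATETIME = "datetime"
    TEXT = "text"
    EMPTY = "empty"


#: widening chains: an integer column may contain decimals, a date
#: column may contain full timestamps, without being "mixed".
_WIDENS = {
    (InferredType.INTEGER, InferredType.DECIMAL): InferredType.DECIMAL,
    (InferredType.DECIMAL, InferredType.INTEGER): InferredType.DECIMAL,
    (InferredType.DATE, InferredType.DATETIME): InferredType.DATETIME,
    (InferredType.DATETIME, InferredType.DATE): InferredType.DATETIME,
}


def infer_cell_type(cell: str) -> InferredType:
    if is_integer(cell):
        return InferredType.INTEGER
    if is_decimal(cell):
        return InferredType.DECIMAL
    if isinstance(check_date(cell), date):
        return InferredType.DATE
    try:
        datetime.fromisoformat(cell)
        return InferredType.DATETIME
    except ValueError:
        return InferredType.TEXT


@dataclass(frozen=True)
class ColumnProfile:
    name: str
    inferred_type: InferredType
    mixed_type: bool
    missing_count: int
    distinct_count: int


def profile_columns(doc: TableDocument,
                    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES
                    ) -> list[ColumnProfile]:
    """Infer a scalar type per column, flagging mixed-type columns.

    Cells equal to a missing code (or empty) are counted as missing and
    never influence the inferred type.  A column is mixed when at least
    two non-missing cells carry conflicting scalar types; integer/decimal
    and date/datetime pairs widen rather than conflict.
    """
    missing = set(missing_codes) | {""}
    profiles = []
    for j, name in enumerate(doc.header):
        cells = [r[j] for r in doc.rows]
        present = [c for c in cells if c.strip() not in missing]
        n_missing = len(cells) - len(present)
        if not present:
            profiles.append(ColumnProfile(name, InferredType.EMPTY, False,
                                          n_missing, 0))
            continue
        current: Optional[InferredType] = None
        mixed = False
        for c in present:
            t = infer_cell_type(c.strip())
            if current is None:
                current = t
            elif t != current:
                widened = _WIDENS.get((current, t))
                if widened is None:
                    mixed = True
                    current = InferredType.TEXT
                else:
                    current = widened
        profiles.append(ColumnProfile(name, current or InferredType.TEXT,
                                      mixed, n_missing, len(set(present))))
    return profiles


# ---------------------------------------------------------------------------
# schema-driven validation
# ---------------------------------------------------------------------------

def _match_columns(doc, schema, report):
    """Map schema field name -> column name present in the document.

    Exact match first; then a forgiving case/whitespace-insensitive
    match that emits a warning suggesting the canonical spelling.
    A schema field named ``*`` is a wildcard matching every otherwise
    unmatched column (used by column-agnostic formats such as the CSV
    guidelines).
    """
    matched: dict[str, str] = {}
    claimed: set[str] = set()
    fuzzy_index = {}
    for col in doc.header:
        fuzzy_index.setdefault(col.strip().casefold(), col)
    for spec in schema.fields:
        if spec.name == "*":
            continue
        if spec.name in doc.header:
            matched[spec.name] = spec.name
            claimed.add(spec.name)
            continue
        cand = fuzzy_index.get(spec.name.strip().casefold())
        if cand is not None and cand not in claimed:
            matched[spec.name] = cand
            claimed.add(cand)
            report.add(issue(
                "HEADER-CASE", file=doc.source_name, row=1, column=cand,
                message=f"column {cand!r} matched field {spec.name!r}; use the "
                        f"canonical name {spec.name!r}",
                schema_id=schema.id))
    return matched, claimed


def _check_cell(spec, cell, *, file, row, column, schema_id, report) -> None:
    """Apply one FieldSpec's type/pattern/bounds/vocabulary checks to a cell."""
    vt = spec.value_type
    if vt == "integer":
        if not is_integer(cell):
            report.add(issue("TYPE-MISMATCH", file=file, row=row, column=column,
                             message=f"expected integer, got {cell!r}",
                             schema_id=schema_id))
            return
        val = float(cell)
    elif vt == "decimal":
        if not is_decimal(cell):
            report.add(issue("TYPE-MISMATCH", file=file, row=row, column=column,
                             message=f"expected decimal, got {cell!r}",
                             schema_id=schema_id))
            return
        val = float(cell)
    elif vt in ("latitude", "longitude"):
        if not is_decimal(cell):
            report.add(issue("TYPE-MISMATCH", file=file, row=row, column=column,
                             message=f"expected decimal degrees, got {cell!r}",
                             schema_id=schema_id))
            return
        val = float(cell)
        if not check_coordinate(val, vt):
            lo, hi = LATITUDE_BOUNDS if vt == "latitude" else LONGITUDE_BOUNDS
            report.add(issue("COORD-RANGE", file=file, row=row, column=column,
                             message=f"{vt} {cell} outside [{lo:g}, {hi:g}]",
                             schema_id=schema_id))
            return
    elif vt == "date":
        if cell == NUMERIC_MISSING_CODE:
            report.add(issue("DATE-MISSING-CODE", file=file, row=row,
                             column=column,
                             message="-9999 in a date column; leave the cell empty",
                             schema_id=schema_id))
            return
        res = check_date(cell)
        if res is DateFailure.BAD_PATTERN:
            report.add(issue("DATE-FORMAT", file=file, row=row, column=column,
                             message=f"{cell!r} is not YYYY-MM-DD",
                             schema_id=schema_id))
            return
        if res is DateFailure.BAD_CALENDAR_DATE:
            report.add(issue("DATE-INVALID", file=file, row=row, column=column,
                             message=f"{cell!r} is not a real calendar date",
                             schema_id=schema_id))
            return
        return
    elif vt == "datetime":
        if cell == NUMERIC_MISSING_CODE:
            report.add(issue("DATE-MISSING-CODE", file=file, row=row,
                             column=column,
                             message="-9999 in a datetime column; leave the cell empty",
                             schema_id=schema_id))
            return
        res = check_datetime(cell)
        if res is DatetimeResult.INVALID:
            report.add(issue("DATETIME-FORMAT", file=file, row=row,
                             column=column,
                             message=f"{cell!r} is not ISO 8601",
                             schema_id=schema_id))
        elif res is DatetimeResult.NAIVE:
            report.add(issue("DATETIME-NAIVE", file=file, row=row,
                             column=column,
                             message=f"{cell!r} has no UTC offset",
                             schema_id=schema_id))
        return
    elif vt == "identifier":
        if not _IDENTIFIER_RE.match(cell):
            report.add(issue("TYPE-MISMATCH", file=file, row=row, column=column,
                             message=f"identifier may not contain whitespace: {cell!r}",
                             schema_id=schema_id))
            return
        val = None
    elif vt == "controlled":
        if cell not in spec.vocabulary:
            report.add(issue("VOCAB-UNKNOWN", file=file, row=row, column=column,
                             message=f"{cell!r} not in vocabulary "
                                     f"{sorted(spec.vocabulary)}",
                             schema_id=schema_id))
        return
    else:  # text
        val = None
    if spec.pattern and not re.fullmatch(spec.pattern, cell):
        report.add(issue("PATTERN-MISMATCH", file=file, row=row, column=column,
                         message=f"{cell!r} does not match /{spec.pattern}/",
                         schema_id=schema_id))
        return
    if spec.bounds is not None and vt in ("integer", "decimal"):
        lo, hi = spec.bounds
        if not (lo <= val <= hi):
            report.add(issue("BOUNDS-RANGE", file=file, row=row, column=column,
                             message=f"{cell} outside [{lo:g}, {hi:g}]",
                             schema_id=schema_id))


def validate_table(doc: TableDocument, schema,
                   missing_codes: Optional[Sequence[str]] = None
                   ) -> ValidationReport:
    """Validate one table against a reporting-format schema.

    Emits one REQ-MISSING error per absent required column, per-cell
    type/pattern/bounds/vocabulary findings, and the table rules the
    schema declares (mixed-type columns, date format).  Columns beyond
    the schema are info-level only: the formats explicitly allow extra
    context columns.  Validation never raises on bad data.
    """
    codes = list(missing_codes) if missing_codes is not None else list(DEFAULT_MISSING_CODES)
    missing = set(codes) | {""}
    report = ValidationReport(files_checked=[doc.source_name],
                              schemas_applied=[schema.id])
    matched, claimed = _match_columns(doc, schema, report)
    has_wildcard = any(f.name == "*" for f in schema.fields)
    specs = {f.name: f for f in schema.fields}

    for spec in schema.fields:
        if spec.name == "*":
            continue
        if spec.requirement == "required" and spec.name not in matched:
            report.add(issue("REQ-MISSING", file=doc.source_name, row=1,
                             column=spec.name,
                             message=f"required column {spec.name!r} is missing",
                             schema_id=schema.id))

    extra = [c for c in doc.header if c not in claimed]
    if not has_wildcard:
        for col in extra:
            report.add(issue("EXTRA-COLUMN", file=doc.source_name, row=1,
                             column=col,
                             message=f"column {col!r} is not part of the "
                                     f"{schema.id} schema (kept as-is)",
                             schema_id=schema.id))

    # per-cell checks for matched columns
    for field_name, col in matched.items():
        spec = specs[field_name]
        j = doc.header.index(col)
        date_missing = {""} if spec.value_type in ("date", "datetime") else missing
        for i, row in enumerate(doc.rows):
            cell = row[j].strip()
            if cell in date_missing and cell != NUMERIC_MISSING_CODE:
                continue
            if spec.value_type not in ("date", "datetime") and cell in missing:
                continue
            _check_cell(spec, cell, file=doc.source_name, row=i + 2,
                        column=col, schema_id=schema.id, report=report)

    # table rules
    rules = set(schema.table_rules)
    if "no-mixed-type-columns" in rules:
        # typed columns already get per-cell TYPE-MISMATCH; the mixed-type
        # rule covers columns the schema does not type (wildcard/extra).
        untyped = set(extra)
        if has_wildcard:
            untyped |= {c for c in doc.header if c not in claimed}
        profiles = {p.name: p for p in profile_columns(doc, codes)}
        for col in doc.header:
            if col in untyped and profiles[col].mixed_type:
                report.add(issue(
                    "MIXED-TYPES", file=doc.source_name, row=1, column=col,
                    message=f"column {col!r} mixes scalar types",
                    schema_id=schema.id))
    if "iso-date-format" in rules:
        # any untyped column whose values look like dates must be YYYY-MM-DD
        untyped_cols = [c for c in doc.header if c not in claimed]
        for col in untyped_cols:
            j = doc.header.index(col)
            for i, row in enumerate(doc.rows):
                cell = row[j].strip()
                if cell in missing:
                    continue
                if re.match(r"^\d{1,4}[/.]\d{1,2}[/.]\d{1,4}$", cell):
                    report.add(issue(
                        "DATE-FORMAT", file=doc.source_name, row=i + 2,
                        column=col,
                        message=f"{cell!r} looks like a date; use YYYY-MM-DD",
                        schema_id=schema.id))
    return report


def summarize_columns(doc: TableDocument,
                      missing_codes: Sequence[str] = DEFAULT_MISSING_CODES
                      ) -> dict[str, dict]:
    """Per-column QA summary: n, n_missing, min/max for numeric columns,
    first/last value for date/datetime columns."""
    missing = set(missing_codes) | {""}
    out: dict[str, dict] = {}
    for j, name in enumerate(doc.header):
        cells = [r[j].strip() for r in doc.rows]
        present = [c for c in cells if c not in missing]
        entry: dict = {"n": len(cells), "n_missing": len(cells) - len(present),
                       "min": None, "max": None, "start": None, "end": None}
        numeric = [float(c) for c in present if is_decimal(c)]
        if numeric and len(numeric) == len(present):
            entry["min"] = min(numeric)
            entry["max"] = max(numeric)
        elif present and all(
                infer_cell_type(c) in (InferredType.DATE, InferredType.DATETIME)
                for c in present):
            entry["start"] = min(present)
            entry["end"] = max(present)
        out[name] = entry
    return out
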