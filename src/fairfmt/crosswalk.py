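"""Term crosswalks: mapping external-standard terminology onto the
harmonized reporting-format vocabulary.

A crosswalk is a plain CSV with columns ``target_format,
source_standard, source_term, target_term, unit_factor, unit_offset,
notes``.  Each row says: in *source_standard*, the column named
*source_term* carries the same information as the harmonized
*target_term*, optionally after the affine unit conversion
``harmonized = raw * unit_factor + unit_offset``.  A classic example is
a water-quality standard reporting timestamps under ``ValueDateTime``
where the harmonized name is simply ``datetime``.

Matching is exact and case-sensitive by default (standards sometimes
differ only by case, and silent folding could merge distinct terms); an
explicit case-insensitive fallback is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .issues import ValidationReport, issue
from .tabular import (TableDocument, is_decimal, read_csv, parse_csv,
                      DEFAULT_MISSING_CODES)

CROSSWALK_COLUMNS = ("target_format", "source_standard", "source_term",
                     "target_term", "unit_factor", "unit_offset", "notes")

#: Sentinel distinct from None for "no entry found".
NOT_FOUND = object()


class CrosswalkError(ValueError):
    pass


@dataclass(frozen=True)
class CrosswalkEntry:
    source_standard: str
    source_term: str
    target_term: str
    unit_factor: float = 1.0
    unit_offset: float = 0.0
    notes: str = ""

    @property
    def is_identity_conversion(self) -> bool:
        return self.unit_factor == 1.0 and self.unit_offset == 0.0


@dataclass
class CrosswalkTable:
    """All crosswalk entries targeting one reporting format."""

    target_format: str
    entries: list[CrosswalkEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.source_standard, e.source_term)
            if key in seen:
                raise CrosswalkError(
                    f"duplicate crosswalk entry for {key} targeting "
                    f"{self.target_format}")
            seen.add(key)

    def standards(self) -> list[str]:
        return sorted({e.source_standard for e in self.entries})

    def for_standard(self, source_standard: str) -> dict[str, CrosswalkEntry]:
        if source_standard not in self.standards():
            raise CrosswalkError(
                f"unknown source standard {source_standard!r}; this crosswalk "
                f"covers: {', '.join(self.standards()) or '(none)'}")
        return {e.source_term: e for e in self.entries
                if e.source_standard == source_standard}

    def orphan_targets(self, schema) -> list[str]:
        """Target terms that do not exist in the target schema's fields."""
        names = set(schema.field_names())
        return sorted({e.target_term for e in self.entries
                       if e.target_term not in names and "*" not in names})


def _parse_factor(cell: str, default: float, context: str) -> float:
    cell = cell.strip()
    if not cell:
        return default
    if not is_decimal(cell):
        raise CrosswalkError(f"{context}: bad numeric value {cell!r}")
    return float(cell)


def load_crosswalk(source: Union[Path, str, TableDocument],
                   schema=None) -> tuple[CrosswalkTable, ValidationReport]:
    """Load one crosswalk CSV.

    Duplicate (standard, term) pairs are load errors.  When the target
    schema is supplied, target terms missing from it are reported as
    load warnings (orphans), not errors — crosswalks may lead schema
    versions slightly.
    """
    if isinstance(source, TableDocument):
        doc = source
    else:
        doc = read_csv(source)
    missing_cols = [c for c in CROSSWALK_COLUMNS if c not in doc.header]
    if missing_cols:
        raise CrosswalkError(
            f"{doc.source_name}: crosswalk is missing columns {missing_cols}")
    formats = {r[doc.header.index("target_format")].strip() for r in doc.rows}
    if len(formats) != 1:
        raise CrosswalkError(
            f"{doc.source_name}: crosswalk must target exactly one format, "
            f"got {sorted(formats)}")
    target_format = formats.pop()
    if schema is not None and schema.id != target_format:
        raise CrosswalkError(
            f"{doc.source_name}: targets {target_format!r}, expected "
            f"{schema.id!r}")
    idx = {c: doc.header.index(c) for c in CROSSWALK_COLUMNS}
    entries = []
    for i, row in enumerate(doc.rows, start=2):
        if not row[idx["source_term"]].strip() or not row[idx["target_term"]].strip():
            raise CrosswalkError(
                f"{doc.source_name}: row {i}: source_term and target_term are "
                f"required")
        entries.append(CrosswalkEntry(
            source_standard=row[idx["source_standard"]].strip(),
            source_term=row[idx["source_term"]].strip(),
            target_term=row[idx["target_term"]].strip(),
            unit_factor=_parse_factor(row[idx["unit_factor"]], 1.0,
                                      f"{doc.source_name}:{i}:unit_factor"),
            unit_offset=_parse_factor(row[idx["unit_offset"]], 0.0,
                                      f"{doc.source_name}:{i}:unit_offset"),
            notes=row[idx["notes"]].strip(),
        ))
    table = CrosswalkTable(target_format, entries)
    report = ValidationReport(files_checked=[doc.source_name])
    if schema is not None:
        for orphan in table.orphan_targets(schema):
            report.add(issue(
                "MAP-UNMAPPED", file=doc.source_name, column=orphan,
                message=f"crosswalk target term {orphan!r} is not a field of "
                        f"schema {schema.id!r}",
                schema_id=schema.id))
    # a non-identity conversion whose source and target share a name would
    # re-apply on repeated translation; refuse it at load time
    for e in entries:
        if e.source_term == e.target_term and not e.is_identity_conversion:
            raise CrosswalkError(
                f"{doc.source_name}: {e.source_term!r}: unit conversion on a "
                f"self-named term is not translatable idempotently")
    return table, report


def packaged_crosswalk_dir() -> Path:
    return Path(resources.files("fairfmt") / "crosswalks")


def load_packaged_crosswalk(target_format: str, schema=None) -> CrosswalkTable:
    path = packaged_crosswalk_dir() / f"{target_format}.csv"
    if not path.is_file():
        raise CrosswalkError(f"no packaged crosswalk for {target_format!r}")
    table, _ = load_crosswalk(path, schema)
    return table


def map_term(table: CrosswalkTable, source_standard: str, term: str,
             case_insensitive: bool = False):
    """Map one external term to its harmonized name.

    Returns the target term, or :data:`NOT_FOUND` (a value, not an
    error).  An unknown source standard *is* an error, listing the
    standards the table covers.
    """
    entries = table.for_standard(source_standard)
    if term in entries:
        return entries[term].target_term
    if case_insensitive:
        folded = {k.casefold(): v for k, v in entries.items()}
        hit = folded.get(term.casefold())
        if hit is not None:
            return hit.target_term
    return NOT_FOUND


def translate_headers(doc: TableDocument, table: CrosswalkTable,
                      source_standard: str, *,
                      case_insensitive: bool = False,
                      schema=None,
                      missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
                      ) -> tuple[TableDocument, ValidationReport]:
    """Rename foreign headers onto the harmonized vocabulary.

    Mapped columns are renamed and unit-converted when the crosswalk
    declares an affine conversion; unmapped columns are preserved
    verbatim and reported.  If two source columns would land on the same
    harmonized name the translation is refused with a MAP-COLLISION
    error and the document returned unchanged.  When the target schema
    is given, the translated table is re-validated in the same report.
    Applying the same translation twice is the identity.
    """
    report = ValidationReport(files_checked=[doc.source_name],
                              schemas_applied=[table.target_format])
    entries = table.for_standard(source_standard)
    missing = set(missing_codes) | {""}

    plan: dict[str, CrosswalkEntry] = {}
    for col in doc.header:
        e = entries.get(col)
        if e is None and case_insensitive:
            folded = {k.casefold(): v for k, v in entries.items()}
            e = folded.get(col.casefold())
        # already-harmonized columns stay put (idempotence)
        if e is not None and e.target_term != col:
            plan[col] = e

    new_names = [plan[c].target_term if c in plan else c for c in doc.header]
    dup = sorted({n for n in new_names if new_names.count(n) > 1
                  and n in {e.target_term for e in plan.values()}})
    if dup:
        for n in dup:
            sources = [c for c in doc.header
                       if (plan.get(c).target_term if c in plan else c) == n]
            report.add(issue(
                "MAP-COLLISION", file=doc.source_name, column=n,
                message=f"columns {sources} would all map to {n!r}; no rename "
                        f"applied"))
        return doc.copy(), report

    out = doc.copy()
    out.header = new_names
    for col, e in plan.items():
        if e.is_identity_conversion:
            continue
        j = doc.header.index(col)
        for row in out.rows:
            cell = row[j].strip()
            if cell in missing or not is_decimal(cell):
                continue
            row[j] = _format_number(float(cell) * e.unit_factor + e.unit_offset)
    for col in doc.header:
        mapped_or_harmonized = col in plan or any(
            e.target_term == col for e in entries.values())
        if not mapped_or_harmonized:
            report.add(issue(
                "MAP-UNMAPPED", file=doc.source_name, column=col,
                message=f"column {col!r} has no crosswalk entry for standard "
                        f"{source_standard!r}; preserved verbatim"))
    if schema is not None:
        from .tabular import validate_table
        report.extend(validate_table(out, schema))
    return out, report


def _format_number(x: float) -> str:
    s = f"{x:.10g}"
    return s
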