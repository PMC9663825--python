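"""Dataset bundles: the set of files submitted together as one archival
dataset, with roles assigned, plus the cross-file consistency checks
that no single-table schema can express (FLMD coverage, sample and
location references, IGSN syntax on referenced identifiers)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .issues import ValidationReport, issue, merge
from .metadata import (ModelArchiveChecklist, evaluate_model_checklist,
                       looks_like_igsn, parse_dataset_metadata_json,
                       parse_flmd, validate_dataset_metadata, validate_igsn)
from .schema import SchemaRegistry, load_registry
from .tabular import (CsvParseError, DEFAULT_MISSING_CODES, TableDocument,
                      read_csv, validate_table)
from .domains import DOMAIN_FORMAT_IDS, validate_amplicon_metadata, validate_domain_table

MANIFEST_NAME = "manifest.json"

ROLES = ("dataset_metadata", "flmd", "data", "sample_metadata",
         "location_metadata", "model_checklist", "amplicon_metadata",
         "sequences")

#: Columns scanned for references into the sample / location registries.
SAMPLE_REF_COLUMNS = ("sample_id", "parent_sample")
LOCATION_REF_COLUMNS = ("location_id", "site_id", "parent_location")


@dataclass(frozen=True)
class BundleFile:
    name: str
    role: str
    schema_id: str = ""


@dataclass
class DatasetBundle:
    root: Path
    files: list[BundleFile] = field(default_factory=list)

    def path(self, name: str) -> Path:
        return self.root / name

    def by_role(self, role: str) -> list[BundleFile]:
        return [f for f in self.files if f.role == role]

    def names(self) -> list[str]:
        return [f.name for f in self.files]

    def to_manifest(self) -> dict:
        return {"files": [{"name": f.name, "role": f.role,
                           "schema_id": f.schema_id} for f in self.files]}


def load_bundle(root) -> DatasetBundle:
    """Assemble a bundle from a directory.

    A ``manifest.json`` (as written by the fixture generator or a
    previous run) is authoritative when present; otherwise roles are
    inferred from file names: ``*flmd*.csv`` is file-level metadata,
    ``dataset_metadata.json`` is dataset metadata, ``samples*.csv`` /
    ``locations*.csv`` are the registries, everything else tabular is
    data under the CSV guidelines.
    """
    root = Path(root)
    manifest = root / MANIFEST_NAME
    if manifest.is_file():
        raw = json.loads(manifest.read_text(encoding="utf-8"))
        files = [BundleFile(f["name"], f["role"], f.get("schema_id", ""))
                 for f in raw["files"]]
        return DatasetBundle(root, files)
    files = []
    for p in sorted(root.iterdir()):
        if p.name == MANIFEST_NAME or p.is_dir():
            continue
        low = p.name.lower()
        if low.endswith(".json") and "metadata" in low:
            files.append(BundleFile(p.name, "dataset_metadata",
                                    "dataset_metadata"))
        elif low.endswith(".csv") and "flmd" in low:
            files.append(BundleFile(p.name, "flmd", "file_level_metadata"))
        elif low.endswith(".csv") and low.startswith("sample"):
            files.append(BundleFile(p.name, "sample_metadata", "sample_metadata"))
        elif low.endswith(".csv") and low.startswith("location"):
            files.append(BundleFile(p.name, "location_metadata",
                                    "location_metadata"))
        elif low.endswith(".csv") and "checklist" in low:
            files.append(BundleFile(p.name, "model_checklist", "model_archiving"))
        elif low.endswith((".fasta", ".fa")):
            files.append(BundleFile(p.name, "sequences", ""))
        elif low.endswith(".csv"):
            sid = _guess_domain_schema(p)
            files.append(BundleFile(p.name, "data", sid or "csv_guidelines"))
    return DatasetBundle(root, files)


def _guess_domain_schema(path: Path) -> str:
    stem = path.stem.lower()
    for sid in DOMAIN_FORMAT_IDS:
        if sid in stem:
            return sid
    return ""


# ---------------------------------------------------------------------------
# cross-file checks
# ---------------------------------------------------------------------------

def crosscheck_bundle(bundle: DatasetBundle,
                      registry: Optional[SchemaRegistry] = None,
                      parsed: Optional[dict[str, TableDocument]] = None
                      ) -> ValidationReport:
    """Checks that span files.

    * FLMD rows naming files absent from the bundle directory -> error;
      files on disk missing from the FLMD -> warning.  The symmetric
      difference of (files on disk) and (files in FLMD) is exactly the
      set of FILE-* issues.
    * sample/location identifiers referenced in data tables but not
      defined in the sample/location registries -> error (checked only
      when the registry table is part of the bundle).
    * identifiers carrying an explicit IGSN prefix get the syntactic
      IGSN check.
    """
    if registry is None:
        registry = load_registry()
    report = ValidationReport()
    parsed = parsed or {}

    def table(name: str) -> Optional[TableDocument]:
        if name not in parsed:
            p = bundle.path(name)
            if not p.is_file():
                return None
            try:
                parsed[name] = read_csv(p)
            except CsvParseError:
                return None
        return parsed.get(name)

    # -- FLMD coverage -------------------------------------------------
    flmd_files = bundle.by_role("flmd")
    on_disk = sorted(p.name for p in bundle.root.iterdir()
                     if p.is_file() and p.name != MANIFEST_NAME)
    for bf in flmd_files:
        doc = table(bf.name)
        if doc is None or not doc.has_column("file_name"):
            continue
        listed = [c.strip() for c in doc.column("file_name") if c.strip()]
        for i, fname in enumerate(listed, start=2):
            if fname not in on_disk:
                report.add(issue(
                    "FILE-MISSING", file=bf.name, row=i, column="file_name",
                    message=f"{fname!r} is described in the file-level "
                            f"metadata but absent from the bundle",
                    schema_id="file_level_metadata"))
        for fname in on_disk:
            if fname not in listed:
                report.add(issue(
                    "FILE-UNDOCUMENTED", file=fname,
                    message=f"{fname!r} has no row in {bf.name}",
                    schema_id="file_level_metadata"))

    # -- referential integrity ------------------------------------------
    sample_ids: Optional[set[str]] = None
    for bf in bundle.by_role("sample_metadata"):
        doc = table(bf.name)
        if doc is not None and doc.has_column("sample_id"):
            sample_ids = (sample_ids or set()) | {
                c.strip() for c in doc.column("sample_id") if c.strip()}
    location_ids: Optional[set[str]] = None
    for bf in bundle.by_role("location_metadata"):
        doc = table(bf.name)
        if doc is not None and doc.has_column("location_id"):
            location_ids = (location_ids or set()) | {
                c.strip() for c in doc.column("location_id") if c.strip()}

    def check_refs(doc: TableDocument, columns: Sequence[str],
                   ids: set[str], registry_name: str) -> None:
        for col in columns:
            if not doc.has_column(col):
                continue
            j = doc.header.index(col)
            for i, row in enumerate(doc.rows, start=2):
                cell = row[j].strip()
                if not cell or cell in DEFAULT_MISSING_CODES:
                    continue
                if cell not in ids:
                    report.add(issue(
                        "REF-UNRESOLVED", file=doc.source_name, row=i,
                        column=col,
                        message=f"{cell!r} (column {col!r}) is not defined in "
                                f"{registry_name}"))

    data_files = bundle.by_role("data")
    for bf in data_files:
        doc = table(bf.name)
        if doc is None:
            continue
        if sample_ids is not None:
            check_refs(doc, SAMPLE_REF_COLUMNS, sample_ids,
                       "the sample metadata table")
        if location_ids is not None:
            check_refs(doc, LOCATION_REF_COLUMNS, location_ids,
                       "the location metadata table")

    # parent pointers inside the registries themselves
    for bf in bundle.by_role("sample_metadata"):
        doc = table(bf.name)
        if doc is not None and sample_ids is not None:
            check_refs(doc, ("parent_sample",), sample_ids,
                       "the sample metadata table")
    for bf in bundle.by_role("location_metadata"):
        doc = table(bf.name)
        if doc is not None and location_ids is not None:
            check_refs(doc, ("parent_location",), location_ids,
                       "the location metadata table")

    # -- IGSN-prefixed identifiers --------------------------------------
    for bf in data_files + bundle.by_role("sample_metadata"):
        doc = table(bf.name)
        if doc is None:
            continue
        for col in ("sample_id",):
            if not doc.has_column(col):
                continue
            j = doc.header.index(col)
            for i, row in enumerate(doc.rows, start=2):
                cell = row[j].strip()
                if looks_like_igsn(cell):
                    res = validate_igsn(cell)
                    if not res.ok:
                        report.add(issue(
                            "IGSN-SYNTAX", file=doc.source_name, row=i,
                            column=col,
                            message=f"{cell!r} is not a valid IGSN "
                                    f"({res.reason})"))
    return report


# ---------------------------------------------------------------------------
# whole-bundle validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: DatasetBundle,
                    registry: Optional[SchemaRegistry] = None
                    ) -> ValidationReport:
    """Validate every file in a bundle under its assigned schema, then
    run the cross-file checks.  Parse failures surface as exceptions;
    bad *data* never does."""
    if registry is None:
        registry = load_registry()
    reports: list[ValidationReport] = []
    parsed: dict[str, TableDocument] = {}
    flmd_missing_codes: dict[str, tuple[str, ...]] = {}

    # FLMD first so its per-file missing codes can feed profiling
    for bf in bundle.by_role("flmd"):
        doc = read_csv(bundle.path(bf.name))
        parsed[bf.name] = doc
        records, rep = parse_flmd(doc, registry)
        reports.append(rep)
        for rec in records:
            if rec.missing_value_codes:
                flmd_missing_codes[rec.file_name] = rec.missing_value_codes

    for bf in bundle.files:
        p = bundle.path(bf.name)
        if bf.role == "dataset_metadata":
            md = parse_dataset_metadata_json(p.read_text(encoding="utf-8"),
                                             source_name=bf.name)
            reports.append(validate_dataset_metadata(md, source_name=bf.name))
        elif bf.role in ("sample_metadata", "location_metadata"):
            doc = parsed.setdefault(bf.name, read_csv(p))
            reports.append(validate_table(doc, registry.get(bf.schema_id)))
        elif bf.role == "model_checklist":
            doc = parsed.setdefault(bf.name, read_csv(p))
            reports.append(validate_table(doc, registry.get("model_archiving")))
            checklist = ModelArchiveChecklist.from_table(doc)
            reports.append(evaluate_model_checklist(checklist,
                                                    source_name=bf.name))
        elif bf.role == "amplicon_metadata":
            doc = parsed.setdefault(bf.name, read_csv(p))
            reports.append(validate_amplicon_metadata(doc))
        elif bf.role == "data":
            doc = parsed.setdefault(bf.name, read_csv(p))
            codes = flmd_missing_codes.get(bf.name)
            missing = (DEFAULT_MISSING_CODES if codes is None
                       else tuple(set(DEFAULT_MISSING_CODES) | set(codes)))
            if bf.schema_id in DOMAIN_FORMAT_IDS:
                reports.append(validate_domain_table(
                    doc, bf.schema_id, registry, missing_codes=missing))
            else:
                sid = bf.schema_id or "csv_guidelines"
                reports.append(validate_table(doc, registry.get(sid),
                                              missing_codes=missing))
    reports.append(crosscheck_bundle(bundle, registry, parsed))
    out = merge(reports)
    for f in bundle.names():
        if f not in out.files_checked:
            out.files_checked.append(f)
    return out
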