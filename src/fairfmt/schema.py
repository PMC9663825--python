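"""Schema language for reporting formats and the packaged registry.

Each reporting format is described by one YAML file: a stable id, a
category (cross-domain or domain-specific), an ordered field list with
requirement levels and value types, declarative table rules, and the
data-type tags the recommender uses.  The packaged registry holds the
eleven community formats: six cross-domain (dataset metadata,
file-level metadata, CSV guidelines, sample metadata, location
metadata, terrestrial model archiving) and five domain-specific
(amplicon abundance, leaf-level gas exchange, soil respiration, water
and soil chemistry, hydrologic monitoring).

The schema language is deliberately declarative only; logic that spans
files (referential checks, FLMD coverage) lives in code, keeping the
schema files portable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

VALUE_TYPES = ("text", "integer", "decimal", "date", "datetime",
               "latitude", "longitude", "identifier", "controlled")
REQUIREMENTS = ("required", "optional")
CATEGORIES = ("cross_domain", "domain_specific")

#: The five published domain data-type tags.
DOMAIN_TAGS = ("amplicon", "leaf_gas_exchange", "soil_respiration",
               "water_soil_chemistry", "hydrologic_monitoring")

#: tag -> domain schema id
TAG_TO_SCHEMA = {
    "amplicon": "amplicon_abundance",
    "leaf_gas_exchange": "leaf_gas_exchange",
    "soil_respiration": "soil_respiration",
    "water_soil_chemistry": "water_soil_chemistry",
    "hydrologic_monitoring": "hydrologic_monitoring",
}

CROSS_DOMAIN_IDS = ("dataset_metadata", "file_level_metadata",
                    "csv_guidelines", "sample_metadata",
                    "location_metadata", "model_archiving")
DOMAIN_IDS = tuple(sorted(TAG_TO_SCHEMA.values()))

_TOKEN_RE = re.compile(r"^[A-Za-z0-9_*][A-Za-z0-9_\-./ ()%]*$")


class SchemaError(ValueError):
    """Malformed schema file or registry invariant violation."""


@dataclass(frozen=True)
class FieldSpec:
    """One column/field of a reporting format."""

    name: str
    requirement: str = "optional"
    value_type: str = "text"
    units: str = ""
    vocabulary: tuple[str, ...] = ()
    pattern: str = ""
    bounds: Optional[tuple[float, float]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("field name must be non-empty")
        if self.requirement not in REQUIREMENTS:
            raise SchemaError(f"{self.name}: bad requirement {self.requirement!r}")
        if self.value_type not in VALUE_TYPES:
            raise SchemaError(f"{self.name}: bad value_type {self.value_type!r}")
        if (self.value_type == "controlled") != bool(self.vocabulary):
            raise SchemaError(
                f"{self.name}: vocabulary must be given exactly when "
                f"value_type is 'controlled'")
        if self.bounds is not None:
            if self.value_type not in ("integer", "decimal", "latitude",
                                       "longitude"):
                raise SchemaError(f"{self.name}: bounds only for numeric types")
            if self.bounds[0] > self.bounds[1]:
                raise SchemaError(f"{self.name}: bounds min > max")


@dataclass(frozen=True)
class ReportingFormatSchema:
    """Machine-readable definition of one reporting format."""

    id: str
    title: str
    category: str
    fields: tuple[FieldSpec, ...]
    table_rules: tuple[str, ...] = ()
    applies_to: tuple[str, ...] = ()
    version: str = "1.0"
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(f"{self.id}: bad category {self.category!r}")
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise SchemaError(f"{self.id}: duplicate field names")
        if not any(f.requirement == "required" for f in self.fields):
            raise SchemaError(f"{self.id}: needs at least one required field")

    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def required_fields(self) -> list[FieldSpec]:
        return [f for f in self.fields if f.requirement == "required"]


@dataclass
class SchemaRegistry:
    """The loaded set of reporting-format schemas.

    Ordering is deterministic: cross-domain schemas first, then
    domain-specific, alphabetical by id within each category.
    """

    schemas: list[ReportingFormatSchema]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.schemas]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate schema ids in registry")
        self.schemas.sort(key=lambda s: (s.category != "cross_domain", s.id))

    def __len__(self) -> int:
        return len(self.schemas)

    def __iter__(self):
        return iter(self.schemas)

    def ids(self) -> list[str]:
        return [s.id for s in self.schemas]

    def get(self, schema_id: str) -> ReportingFormatSchema:
        for s in self.schemas:
            if s.id == schema_id:
                return s
        raise KeyError(f"unknown format id {schema_id!r}; known: "
                       f"{', '.join(self.ids())}")

    def by_category(self, category: str) -> list[ReportingFormatSchema]:
        return [s for s in self.schemas if s.category == category]

    def assert_published_registry(self) -> None:
        """Invariants of the packaged registry: 11 = 6 + 5."""
        n_cross = len(self.by_category("cross_domain"))
        n_domain = len(self.by_category("domain_specific"))
        if (len(self), n_cross, n_domain) != (11, 6, 5):
            raise SchemaError(
                f"registry must hold 11 schemas (6 cross-domain + 5 "
                f"domain-specific); got {len(self)} = {n_cross} + {n_domain}")
        for sid in CROSS_DOMAIN_IDS + DOMAIN_IDS:
            self.get(sid)


def _parse_field(raw: dict, context: str) -> FieldSpec:
    if not isinstance(raw, dict) or "name" not in raw:
        raise SchemaError(f"{context}: field entry must be a mapping with a name")
    bounds = raw.get("bounds")
    return FieldSpec(
        name=str(raw["name"]),
        requirement=raw.get("requirement", "optional"),
        value_type=raw.get("value_type", "text"),
        units=str(raw.get("units", "") or ""),
        vocabulary=tuple(str(v) for v in raw.get("vocabulary", []) or []),
        pattern=str(raw.get("pattern", "") or ""),
        bounds=(float(bounds[0]), float(bounds[1])) if bounds else None,
        description=str(raw.get("description", "") or ""),
    )


def parse_schema_text(text: str, source: str = "<string>") -> ReportingFormatSchema:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{source}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{source}: schema file must be a mapping")
    for key in ("id", "title", "category", "fields"):
        if key not in raw:
            raise SchemaError(f"{source}: missing key {key!r}")
    try:
        return ReportingFormatSchema(
            id=str(raw["id"]),
            title=str(raw["title"]),
            category=str(raw["category"]),
            fields=tuple(_parse_field(f, source) for f in raw["fields"]),
            table_rules=tuple(raw.get("table_rules", []) or []),
            applies_to=tuple(raw.get("applies_to", []) or []),
            version=str(raw.get("version", "1.0")),
            description=str(raw.get("description", "") or ""),
        )
    except SchemaError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def packaged_schema_dir() -> Path:
    return Path(resources.files("fairfmt") / "schemas")


def load_registry(schema_dir: Optional[Path] = None, *,
                  require_published: Optional[bool] = None) -> SchemaRegistry:
    """Load all ``*.yaml`` schema files from a directory.

    With no argument the packaged registry is loaded and its published
    invariants (11 schemas, 6 cross-domain + 5 domain-specific) are
    asserted.  An empty directory is a load error, never an empty
    registry.
    """
    packaged = schema_dir is None
    directory = packaged_schema_dir() if packaged else Path(schema_dir)
    if require_published is None:
        require_published = packaged
    if not directory.is_dir():
        raise SchemaError(f"schema directory {directory} does not exist")
    files = sorted(directory.glob("*.yaml"))
    if not files:
        raise SchemaError(f"no schema files found in {directory}")
    schemas = []
    for path in files:
        schemas.append(parse_schema_text(path.read_text(encoding="utf-8"),
                                         source=path.name))
    registry = SchemaRegistry(schemas)
    if require_published:
        registry.assert_published_registry()
    return registry


# ---------------------------------------------------------------------------
# applicability workflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetProfile:
    """What a dataset contains, for the format recommender."""

    has_tabular_data: bool = False
    has_samples: bool = False
    has_locations: bool = False
    has_model_output: bool = False
    domain_data_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.domain_data_types) - set(DOMAIN_TAGS)
        if unknown:
            raise ValueError(
                f"unknown domain data type(s) {sorted(unknown)}; valid tags: "
                f"{', '.join(DOMAIN_TAGS)}")


def recommend_formats(profile: DatasetProfile,
                      registry: Optional[SchemaRegistry] = None) -> list[str]:
    """Walk the applicability workflow for a dataset profile.

    Every dataset needs citation metadata, so ``dataset_metadata`` is
    always recommended.  Tabular data pulls in file-level metadata and
    the CSV guidelines; samples, locations and model output pull in
    their cross-domain formats; each domain data type adds its format.
    Monotone by construction: adding a flag or tag never removes a
    recommendation.
    """
    if registry is None:
        registry = load_registry()
    recs = ["dataset_metadata"]
    if profile.has_tabular_data:
        recs += ["file_level_metadata", "csv_guidelines"]
    if profile.has_samples:
        recs.append("sample_metadata")
    if profile.has_locations:
        recs.append("location_metadata")
    if profile.has_model_output:
        recs.append("model_archiving")
    for tag in sorted(profile.domain_data_types):
        recs.append(TAG_TO_SCHEMA[tag])
    for sid in recs:
        registry.get(sid)  # every recommendation must resolve
    return recs
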