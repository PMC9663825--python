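"""Synthetic dataset-bundle generator with controlled fault injection.

The generator emulates the *structure* the reporting formats prescribe
(columns, types, cross-file wiring), not realistic scientific signal:
dates are uniform in the requested range, coordinates uniform in the
requested box, amplicon counts gamma-Poisson (negative binomial) with
fixed dispersion, and sequences uniform over ACGT.  All randomness
flows from one seeded generator, so the same spec and seed produce
byte-identical bundles.

Every issue code marked mutable in the catalogue has a fault generator
here.  A mutation returns a ledger of exactly the issues it introduced,
which the round-trip property checks against the validator's output:
generate -> mutate -> validate must detect precisely the injected
faults and nothing else.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .bundle import MANIFEST_NAME, BundleFile, DatasetBundle
from .issues import CATALOGUE, MUTABLE_CODES
from .schema import TAG_TO_SCHEMA, load_registry
from .tabular import Dialect, TableDocument, read_csv, write_csv

DEFAULT_N_ROWS = 20
DEFAULT_N_SAMPLES = 5
DEFAULT_COORD_BOX = (37.0, 38.0, -123.0, -122.0)  # lat_min, lat_max, lon_min, lon_max
DEFAULT_DATE_RANGE = ("2021-04-01", "2021-09-30")

ALL_FORMAT_IDS = ("dataset_metadata", "file_level_metadata", "csv_guidelines",
                  "sample_metadata", "location_metadata", "model_archiving",
                  "amplicon_abundance", "leaf_gas_exchange", "soil_respiration",
                  "water_soil_chemistry", "hydrologic_monitoring")

#: gamma-Poisson (negative binomial) parameters for amplicon counts
NB_MEAN = 25.0
NB_DISPERSION = 0.8  # gamma shape; smaller = more overdispersed


class FixtureError(ValueError):
    pass


class MutationError(ValueError):
    """Requested fault cannot be injected (no generator, or the bundle
    lacks the file the generator needs)."""


@dataclass(frozen=True)
class ExpectedIssue:
    """Ledger entry: the signature of one injected issue."""

    code: str
    file: str
    row: Optional[int] = None
    column: str = ""

    def signature(self) -> tuple:
        return (self.code, self.file, self.row, self.column)

    def to_dict(self) -> dict:
        return {"code": self.code, "file": self.file, "row": self.row,
                "column": self.column}


@dataclass
class FixtureSpec:
    formats: Sequence[str] = ALL_FORMAT_IDS
    n_rows: int = DEFAULT_N_ROWS
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    violations: Sequence[tuple[str, int]] = ()
    coord_box: tuple[float, float, float, float] = DEFAULT_COORD_BOX
    date_range: tuple[str, str] = DEFAULT_DATE_RANGE

    def __post_init__(self) -> None:
        known = set(ALL_FORMAT_IDS)
        bad = [f for f in self.formats if f not in known]
        if bad:
            raise FixtureError(f"unknown format id(s) {bad}; known: "
                               f"{', '.join(ALL_FORMAT_IDS)}")
        for code, count in self.violations:
            if code not in CATALOGUE:
                raise FixtureError(f"unknown issue code {code!r}")
            if not CATALOGUE[code].mutable:
                raise FixtureError(f"issue code {code!r} has no fault generator; "
                                   f"mutable codes: {', '.join(MUTABLE_CODES)}")
            if count < 1:
                raise FixtureError("violation count must be >= 1")


# ---------------------------------------------------------------------------
# random primitives
# ---------------------------------------------------------------------------

def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; lambdas here are small (tens)
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def _nbinom(rng: random.Random) -> int:
    lam = rng.gammavariate(NB_DISPERSION, NB_MEAN / NB_DISPERSION)
    return _poisson(rng, lam)


def _dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _dates(rng: random.Random, spec: FixtureSpec, n: int) -> list[str]:
    from datetime import date, timedelta
    d0 = date.fromisoformat(spec.date_range[0])
    d1 = date.fromisoformat(spec.date_range[1])
    span = (d1 - d0).days
    return sorted((d0 + timedelta(days=rng.randrange(span + 1))).isoformat()
                  for _ in range(n))


# ---------------------------------------------------------------------------
# per-file emitters
# ---------------------------------------------------------------------------

def _doc(name: str, header: list[str], rows: list[list[str]]) -> TableDocument:
    return TableDocument(name, header, rows, dialect=Dialect())


def _make_dataset_metadata(spec: FixtureSpec, rng: random.Random) -> str:
    lat = round(rng.uniform(spec.coord_box[0], spec.coord_box[1]), 5)
    lon = round(rng.uniform(spec.coord_box[2], spec.coord_box[3]), 5)
    doc = {
        "title": "Synthetic multi-format fixture dataset for reporting-format "
                 "validation exercises",
        "abstract": "A generated dataset bundle exercising the harmonized "
                    "(meta)data reporting formats: tabular data, samples, "
                    "locations, domain tables, and file-level metadata. "
                    "Contains no real observations.",
        "creators": [
            {"name": "Ada Fixture", "affiliation": "Synthetic Data Institute",
             "identifier": "https://orcid.org/0000-0002-1825-0097"},
            {"name": "Grace Generator", "affiliation": "Synthetic Data Institute",
             "identifier": ""},
        ],
        "keywords": ["synthetic", "validation", "reporting format"],
        "temporal_coverage": {"start_date": spec.date_range[0],
                              "end_date": spec.date_range[1]},
        "spatial_coverage": [{"latitude": lat, "longitude": lon,
                              "description": "generated study site"}],
        "funding": "Synthetic Science Foundation grant 0000",
        "related_identifiers": ["doi:10.0000/synthetic.fixture"],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _sample_ids(spec: FixtureSpec) -> list[str]:
    return [f"S-{i:03d}" for i in range(1, spec.n_samples + 1)]


def _location_ids(spec: FixtureSpec) -> list[str]:
    return [f"LOC-{i:02d}" for i in range(1, min(spec.n_samples, 3) + 1)]


def _make_samples(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    header = ["sample_id", "sample_name", "material", "collection_date",
              "latitude", "longitude", "parent_sample"]
    dates = _dates(rng, spec, spec.n_samples)
    rows = []
    for sid, d in zip(_sample_ids(spec), dates):
        rows.append([
            sid, f"core {sid.lower()}",
            rng.choice(["soil", "water", "sediment"]), d,
            f"{rng.uniform(spec.coord_box[0], spec.coord_box[1]):.5f}",
            f"{rng.uniform(spec.coord_box[2], spec.coord_box[3]):.5f}",
            "",
        ])
    return _doc("samples.csv", header, rows)


def _make_locations(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    header = ["location_id", "location_name", "latitude", "longitude",
              "elevation_m", "description", "parent_location"]
    rows = []
    for lid in _location_ids(spec):
        rows.append([
            lid, f"site {lid.lower()}",
            f"{rng.uniform(spec.coord_box[0], spec.coord_box[1]):.5f}",
            f"{rng.uniform(spec.coord_box[2], spec.coord_box[3]):.5f}",
            f"{rng.uniform(10, 900):.1f}", "generated monitoring site", "",
        ])
    return _doc("locations.csv", header, rows)


def _make_generic_data(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    header = ["plot_id", "date", "biomass_g", "stem_count"]
    dates = _dates(rng, spec, spec.n_rows)
    rows = []
    for i in range(spec.n_rows):
        biomass = "-9999" if rng.random() < 0.1 else f"{rng.uniform(5, 120):.2f}"
        rows.append([f"plot_{chr(65 + i % 4)}", dates[i], biomass,
                     str(rng.randrange(1, 40))])
    return _doc("data.csv", header, rows)


def _make_model_checklist(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    from .metadata import CHECKLIST_ITEMS
    header = ["item", "status", "evidence_file"]
    rows = [[item, "present", ""] for item in CHECKLIST_ITEMS]
    return _doc("model_checklist.csv", header, rows)


def _make_amplicon(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    n_feat = max(4, spec.n_rows // 2)
    sample_cols = [f"samp_{i:02d}" for i in range(1, spec.n_samples + 1)]
    header = ["feature_id", "representative_sequence"] + sample_cols
    rows = []
    for i in range(1, n_feat + 1):
        rows.append([f"ASV_{i:04d}", _dna(rng, 60)]
                    + [str(_nbinom(rng)) for _ in sample_cols])
    return _doc("amplicon_abundance.csv", header, rows)


def _make_amplicon_metadata(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    header = ["section", "attribute", "value"]
    rows = [
        ["sequencing", "target_gene", "16S rRNA"],
        ["sequencing", "target_region", "V4"],
        ["sequencing", "primers", "515F/806R"],
        ["sequencing", "platform", "Illumina MiSeq"],
        ["sequencing", "run_identifier", "RUN-0001"],
        ["bioinformatics", "pipeline", "qiime2-2023.2"],
        ["bioinformatics", "denoising_method", "dada2"],
        ["bioinformatics", "truncation_length", "150"],
        ["bioinformatics", "quality_threshold", "20"],
        ["bioinformatics", "reference_database", "SILVA 138"],
    ]
    return _doc("amplicon_metadata.csv", header, rows)


def _make_leaf_gas_exchange(spec: FixtureSpec, rng: random.Random,
                            sample_ids: Optional[list[str]]) -> TableDocument:
    header = ["record_id", "A", "gsw", "Ci", "Tleaf", "Qin", "instrument",
              "raw_or_processed"]
    if sample_ids:
        header.insert(1, "sample_id")
    rows = []
    for i in range(1, spec.n_rows + 1):
        row = [f"REC-{i:04d}",
               f"{rng.uniform(2, 30):.3f}", f"{rng.uniform(0.05, 0.6):.4f}",
               f"{rng.uniform(150, 350):.1f}", f"{rng.uniform(15, 35):.2f}",
               f"{rng.uniform(0, 2000):.1f}", "li6800", "processed"]
        if sample_ids:
            row.insert(1, rng.choice(sample_ids))
        rows.append(row)
    return _doc("leaf_gas_exchange.csv", header, rows)


def _make_soil_respiration(spec: FixtureSpec, rng: random.Random) -> TableDocument:
    header = ["timestamp", "chamber_id", "flux", "gas_species",
              "soil_temperature", "soil_moisture"]
    rows = []
    base = f"{spec.date_range[0]}T06:00:00+00:00"
    from datetime import datetime, timedelta
    t = datetime.fromisoformat(base)
    for i in range(spec.n_rows):
        t = t + timedelta(minutes=30)
        rows.append([t.isoformat(), f"CH-{1 + i % 2}",
                     f"{rng.uniform(0.5, 8.0):.3f}",
                     rng.choice(["CO2", "CO2", "CO2", "CH4"]),
                     f"{rng.uniform(8, 25):.2f}", f"{rng.uniform(0.1, 0.45):.3f}"])
    return _doc("soil_respiration.csv", header, rows)


def _make_hydro(spec: FixtureSpec, rng: random.Random,
                site_ids: Optional[list[str]]) -> TableDocument:
    header = ["datetime", "site_id", "water_level", "temperature", "pH", "notes"]
    site = site_ids[0] if site_ids else "SITE-1"
    rows = []
    from datetime import datetime, timedelta
    t = datetime.fromisoformat(f"{spec.date_range[0]}T00:00:00+00:00")
    for i in range(spec.n_rows):
        t = t + timedelta(minutes=15)
        level = "-9999" if rng.random() < 0.05 else f"{rng.uniform(0.2, 3.5):.3f}"
        rows.append([t.isoformat(), site, level,
                     f"{rng.uniform(4, 22):.2f}", f"{rng.uniform(5.5, 8.5):.2f}",
                     ""])
    return _doc("hydrologic_monitoring.csv", header, rows)


def _make_water_chem(spec: FixtureSpec, rng: random.Random,
                     sample_ids: Optional[list[str]]) -> TableDocument:
    from .domains import ANALYTE_VOCABULARY
    header = ["sample_id", "igsn", "analyte", "value", "unit", "method",
              "below_detection_flag", "detection_limit", "matrix"]
    analytes = sorted(ANALYTE_VOCABULARY)
    ids = sample_ids or [f"S-{i:03d}" for i in range(1, spec.n_samples + 1)]
    rows = []
    for i in range(spec.n_rows):
        below = rng.random() < 0.1
        rows.append([
            rng.choice(ids),
            f"IGSN:IEFXT{i:04d}",
            rng.choice(analytes),
            "-9999" if below else f"{rng.uniform(0.01, 50):.4f}",
            "mg/L",
            "ion chromatography",
            "TRUE" if below else "FALSE",
            "0.01" if below else "",
            rng.choice(["water", "soil", "sediment"]),
        ])
    return _doc("water_soil_chemistry.csv", header, rows)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(spec: FixtureSpec, out_dir) -> DatasetBundle:
    """Generate a dataset bundle for the requested formats.

    The bundle always contains dataset metadata and an FLMD table
    covering every emitted file (including the FLMD itself); each
    requested format adds its table.  With no violations requested the
    bundle validates with zero issues under all requested schemas.
    Output bytes are fully determined by the spec (including its seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    formats = list(spec.formats)

    sample_ids = _sample_ids(spec) if "sample_metadata" in formats else None
    location_ids = (_location_ids(spec)
                    if "location_metadata" in formats else None)

    files: list[BundleFile] = []
    docs: list[TableDocument] = []

    def emit(doc: TableDocument, role: str, schema_id: str) -> None:
        docs.append(doc)
        files.append(BundleFile(doc.source_name, role, schema_id))

    md_text = _make_dataset_metadata(spec, rng)
    files.append(BundleFile("dataset_metadata.json", "dataset_metadata",
                            "dataset_metadata"))
    if "csv_guidelines" in formats:
        emit(_make_generic_data(spec, rng), "data", "csv_guidelines")
    if "sample_metadata" in formats:
        emit(_make_samples(spec, rng), "sample_metadata", "sample_metadata")
    if "location_metadata" in formats:
        emit(_make_locations(spec, rng), "location_metadata",
             "location_metadata")
    if "model_archiving" in formats:
        emit(_make_model_checklist(spec, rng), "model_checklist",
             "model_archiving")
    if "amplicon_abundance" in formats:
        emit(_make_amplicon(spec, rng), "data", "amplicon_abundance")
        emit(_make_amplicon_metadata(spec, rng), "amplicon_metadata", "")
    if "leaf_gas_exchange" in formats:
        emit(_make_leaf_gas_exchange(spec, rng, sample_ids), "data",
             "leaf_gas_exchange")
    if "soil_respiration" in formats:
        emit(_make_soil_respiration(spec, rng), "data", "soil_respiration")
    if "water_soil_chemistry" in formats:
        emit(_make_water_chem(spec, rng, sample_ids), "data",
             "water_soil_chemistry")
    if "hydrologic_monitoring" in formats:
        emit(_make_hydro(spec, rng, location_ids), "data",
             "hydrologic_monitoring")

    # FLMD covers every file in the bundle, itself included
    all_names = ["dataset_metadata.json", "flmd.csv"] + [d.source_name
                                                         for d in docs]
    flmd_rows = []
    descriptions = {
        "dataset_metadata.json": ("dataset-level citation metadata", "json", ""),
        "flmd.csv": ("file-level metadata for this bundle", "csv", ""),
        "data.csv": ("generic tabular observations", "csv", "-9999"),
        "samples.csv": ("sample registry", "csv", ""),
        "locations.csv": ("research location registry", "csv", ""),
        "model_checklist.csv": ("model archiving checklist", "csv", ""),
        "amplicon_abundance.csv": ("amplicon feature counts", "csv", "-9999"),
        "amplicon_metadata.csv": ("sequencing and bioinformatics metadata",
                                  "csv", ""),
        "leaf_gas_exchange.csv": ("harmonized leaf gas exchange records",
                                  "csv", "-9999"),
        "soil_respiration.csv": ("chamber flux time series", "csv", "-9999"),
        "water_soil_chemistry.csv": ("sample chemistry results", "csv",
                                     "-9999"),
        "hydrologic_monitoring.csv": ("sonde time series", "csv", "-9999"),
    }
    for name in all_names:
        desc, fmt, codes = descriptions.get(name, ("bundle file", "csv", ""))
        flmd_rows.append([name, desc, fmt, "1", codes, ""])
    flmd = _doc("flmd.csv", ["file_name", "file_description", "file_format",
                             "column_or_row_name_position",
                             "missing_value_codes", "notes"], flmd_rows)
    files.insert(1, BundleFile("flmd.csv", "flmd", "file_level_metadata"))

    (out / "dataset_metadata.json").write_text(md_text, encoding="utf-8")
    write_csv(flmd, out / "flmd.csv")
    for doc in docs:
        write_csv(doc, out / doc.source_name)

    bundle = DatasetBundle(out, files)
    ledger: list[ExpectedIssue] = []
    mrng = random.Random(spec.seed + 10_007)
    for code, count in spec.violations:
        for _ in range(count):
            ledger.extend(_apply_mutation(bundle, code, mrng))
    manifest = bundle.to_manifest()
    manifest["seed"] = spec.seed
    manifest["n_rows"] = spec.n_rows
    manifest["injected_issues"] = [e.to_dict() for e in ledger]
    (out / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return bundle


# ---------------------------------------------------------------------------
# fault injection
# ---------------------------------------------------------------------------

def _load(bundle: DatasetBundle, name: str) -> TableDocument:
    p = bundle.path(name)
    if not p.is_file():
        raise MutationError(f"bundle has no file {name!r} to mutate")
    return read_csv(p)


def _save(bundle: DatasetBundle, doc: TableDocument) -> None:
    write_csv(doc, bundle.path(doc.source_name))


def _cell_mutator(file: str, column: str, new_value, code: str,
                  column_level: bool = False) -> Callable:
    """Build a mutator that rewrites one cell and expects one issue.

    Column-level findings (mixed types) are reported against the header
    row rather than the mutated cell.
    """

    def mutate(bundle: DatasetBundle, rng: random.Random) -> list[ExpectedIssue]:
        doc = _load(bundle, file)
        if not doc.has_column(column):
            raise MutationError(f"{file} has no column {column!r}")
        j = doc.header.index(column)
        i = rng.randrange(doc.n_rows)
        value = new_value(doc, i, rng) if callable(new_value) else new_value
        doc.rows[i][j] = value
        _save(bundle, doc)
        return [ExpectedIssue(code, file, 1 if column_level else i + 2, column)]

    return mutate


def _mutate_req_missing(bundle, rng):
    doc = _load(bundle, "water_soil_chemistry.csv")
    j = doc.header.index("unit")
    doc.header.pop(j)
    for row in doc.rows:
        row.pop(j)
    _save(bundle, doc)
    return [ExpectedIssue("REQ-MISSING", "water_soil_chemistry.csv", 1, "unit")]


def _mutate_len_short(bundle, rng):
    p = bundle.path("dataset_metadata.json")
    if not p.is_file():
        raise MutationError("bundle has no dataset_metadata.json")
    raw = json.loads(p.read_text(encoding="utf-8"))
    raw["abstract"] = "Too short."
    p.write_text(json.dumps(raw, indent=2, sort_keys=True) + "\n",
                 encoding="utf-8")
    return [ExpectedIssue("LEN-SHORT", "dataset_metadata.json", None,
                          "abstract")]


def _mutate_dup_file(bundle, rng):
    doc = _load(bundle, "flmd.csv")
    i = rng.randrange(doc.n_rows)
    doc.rows.append(list(doc.rows[i]))
    _save(bundle, doc)
    return [ExpectedIssue("DUP-FILE", "flmd.csv", doc.n_rows + 1, "file_name")]


def _mutate_file_missing(bundle, rng):
    doc = _load(bundle, "flmd.csv")
    doc.rows.append(["ghost.csv", "file that does not exist", "csv", "1", "",
                     ""])
    _save(bundle, doc)
    return [ExpectedIssue("FILE-MISSING", "flmd.csv", doc.n_rows + 1,
                          "file_name")]


def _mutate_file_undocumented(bundle, rng):
    stray = bundle.path("orphan.csv")
    stray.write_text("a,b\n1,2\n", encoding="utf-8")
    return [ExpectedIssue("FILE-UNDOCUMENTED", "orphan.csv", None, "")]


def _mutate_dup_feature(bundle, rng):
    doc = _load(bundle, "amplicon_abundance.csv")
    if doc.n_rows < 2:
        raise MutationError("amplicon table too small to duplicate a feature")
    j = doc.header.index("feature_id")
    src = rng.randrange(doc.n_rows - 1)
    dst = rng.randrange(src + 1, doc.n_rows)
    doc.rows[dst][j] = doc.rows[src][j]
    _save(bundle, doc)
    return [ExpectedIssue("DUP-FEATURE", "amplicon_abundance.csv", dst + 2,
                          "feature_id")]


def _mutate_time_order(bundle, rng):
    doc = _load(bundle, "hydrologic_monitoring.csv")
    if doc.n_rows < 3:
        raise MutationError("hydro series too short to reorder")
    j = doc.header.index("datetime")
    i = rng.randrange(doc.n_rows - 1)
    doc.rows[i][j], doc.rows[i + 1][j] = doc.rows[i + 1][j], doc.rows[i][j]
    _save(bundle, doc)
    return [ExpectedIssue("TIME-ORDER", "hydrologic_monitoring.csv", i + 3,
                          "datetime")]


def _mutate_time_dup(bundle, rng):
    doc = _load(bundle, "hydrologic_monitoring.csv")
    if doc.n_rows < 2:
        raise MutationError("hydro series too short to duplicate a timestamp")
    j = doc.header.index("datetime")
    i = rng.randrange(1, doc.n_rows)
    doc.rows[i][j] = doc.rows[i - 1][j]
    _save(bundle, doc)
    return [ExpectedIssue("TIME-DUP", "hydrologic_monitoring.csv", i + 2,
                          "datetime")]


def _seq_invalid(doc, i, rng):
    j = doc.header.index("representative_sequence")
    return doc.rows[i][j] + "Z"


def _seq_iupac(doc, i, rng):
    j = doc.header.index("representative_sequence")
    return doc.rows[i][j][:-1] + "R"


MUTATORS: dict[str, Callable] = {
    "REQ-MISSING": _mutate_req_missing,
    "TYPE-MISMATCH": _cell_mutator("leaf_gas_exchange.csv", "A",
                                   "not_a_number", "TYPE-MISMATCH"),
    "MIXED-TYPES": _cell_mutator("data.csv", "biomass_g", "abc",
                                 "MIXED-TYPES", column_level=True),
    "VOCAB-UNKNOWN": _cell_mutator("soil_respiration.csv", "gas_species",
                                   "O3", "VOCAB-UNKNOWN"),
    "BOUNDS-RANGE": _cell_mutator("hydrologic_monitoring.csv", "pH", "20.0",
                                  "BOUNDS-RANGE"),
    "COORD-RANGE": _cell_mutator("locations.csv", "latitude", "95.0",
                                 "COORD-RANGE"),
    "DATE-FORMAT": _cell_mutator("samples.csv", "collection_date",
                                 "03/05/2021", "DATE-FORMAT"),
    "DATE-INVALID": _cell_mutator("samples.csv", "collection_date",
                                  "2021-02-30", "DATE-INVALID"),
    "LEN-SHORT": _mutate_len_short,
    "DUP-FILE": _mutate_dup_file,
    "FILE-MISSING": _mutate_file_missing,
    "FILE-UNDOCUMENTED": _mutate_file_undocumented,
    "REF-UNRESOLVED": _cell_mutator("water_soil_chemistry.csv", "sample_id",
                                    "S-GHOST", "REF-UNRESOLVED"),
    "IGSN-SYNTAX": _cell_mutator("water_soil_chemistry.csv", "igsn",
                                 "IGSN:X1", "IGSN-SYNTAX"),
    "NEG-COUNT": _cell_mutator("amplicon_abundance.csv", "samp_01", "-3",
                               "NEG-COUNT"),
    "DUP-FEATURE": _mutate_dup_feature,
    "SEQ-INVALID": _cell_mutator("amplicon_abundance.csv",
                                 "representative_sequence", _seq_invalid,
                                 "SEQ-INVALID"),
    "SEQ-IUPAC": _cell_mutator("amplicon_abundance.csv",
                               "representative_sequence", _seq_iupac,
                               "SEQ-IUPAC"),
    "TIME-ORDER": _mutate_time_order,
    "TIME-DUP": _mutate_time_dup,
    "LT-EMBEDDED": _cell_mutator("water_soil_chemistry.csv", "value", "<0.5",
                                 "LT-EMBEDDED"),
    "ANALYTE-UNKNOWN": _cell_mutator("water_soil_chemistry.csv", "analyte",
                                     "unobtainium", "ANALYTE-UNKNOWN"),
}


def _apply_mutation(bundle: DatasetBundle, code: str,
                    rng: random.Random) -> list[ExpectedIssue]:
    if code not in MUTATORS:
        raise MutationError(
            f"no fault generator for issue code {code!r}; mutable codes: "
            f"{', '.join(MUTABLE_CODES)}")
    mutator = MUTATORS[code]
    if code == "FILE-UNDOCUMENTED":
        ledger = mutator(bundle, rng)
        # the stray file is on disk but deliberately outside the manifest
        return ledger
    return mutator(bundle, rng)


def mutate_bundle(bundle: DatasetBundle, issue_code: str, rng_seed: int
                  ) -> list[ExpectedIssue]:
    """Inject one fault into a (valid) bundle, in place.

    Returns the ledger of exactly the issues the mutation introduces;
    validating the mutated bundle reports precisely these in addition
    to whatever the bundle reported before.
    """
    rng = random.Random(rng_seed)
    return _apply_mutation(bundle, issue_code, rng)
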