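# Methods

## The schema model

Each reporting format is one YAML file declaring an id, a category
(`cross_domain` or `domain_specific`), an ordered list of field
specifications, declarative table rules, and the data-type tags the
recommender uses. A field specification carries a requirement level
(`required`/`optional`), a value type (`text`, `integer`, `decimal`,
`date`, `datetime`, `latitude`, `longitude`, `identifier`,
`controlled`), optional units, a vocabulary (exactly when the type is
`controlled`), an optional regular expression, and optional numeric
bounds. The registry loader asserts the published invariants — exactly
11 schemas, partitioned 6 cross-domain / 5 domain-specific, each with
at least one required field — and orders schemas deterministically
(cross-domain first, alphabetical within category).

The schema language is declarative only. Anything that spans files
(file-level-metadata coverage, sample/location references) lives in
`bundle.py`, so the schema files remain portable data.

**The wildcard field.** The CSV-guidelines format constrains *how*
columns are formatted, not *which* columns exist. Its schema therefore
declares a single required wildcard field `*` that matches every
column: the requirement reduces to "a header of at least one named
column", and all substance sits in the table rules. The amplicon
schema uses an optional wildcard for its per-sample count columns.
Wildcard-matched columns are exempt from extra-column reporting but
remain subject to the column-agnostic table rules.

Field inventories are the minimal defensible core for each format and
the schemas are versioned (`1.1`), so lists can grow without code
change. The leaf gas-exchange variable names (`A`, `gsw`, `Ci`,
`Tleaf`, `Qin`) follow the community's instrument-derived terminology;
the packaged 10-instrument translation table is curated data, not
code, and is a synthetic reconstruction of typical instrument column
naming rather than a copy of any vendor manual.

## Tabular validation

Parsing is RFC 4180 (comma, double-quote escaping, `\n` or `\r\n`),
UTF-8 with a latin-1 fallback, and keeps cells verbatim: typing is a
validation concern, not a parsing one. Ragged rows and empty files are
parse errors, never silently repaired — a deliberately hard line,
since silent padding is how mixed-up columns enter archives. The
standard-library `csv` module does the dialect work; DataFrame readers
were avoided because they pad ragged rows and coerce types before
validation can see the original cells.

Validation emits coded issues at 1-based locations counting the header
as row 1 (what users see in a spreadsheet). Severities: errors fail a
bundle, warnings and info do not. Key behaviours:

- required columns match case-sensitively; a case/whitespace-folded
  match is accepted with a `HEADER-CASE` warning naming the canonical
  spelling;
- columns beyond the schema are `EXTRA-COLUMN` info, never errors —
  the formats explicitly permit extra context columns;
- missing codes (`-9999`, empty, `N/A` by default; extensible per file
  via the file-level metadata) are excluded from all type checks and
  from profiling, so a sentinel never produces a numeric type error;
- dates must be zero-padded `YYYY-MM-DD` real calendar dates, with
  separate failure reasons for shape (`DATE-FORMAT`) and calendar
  (`DATE-INVALID`); `-9999` in a date/datetime column warns
  (`DATE-MISSING-CODE`) — the sentinel convention is numeric, date
  cells should be left empty;
- datetimes are ISO 8601; naive timestamps warn rather than error,
  since the formats mandate the representation but not a timezone
  policy;
- coordinates are closed-interval checks: latitude in [−90, 90],
  longitude in [−180, 180];
- the mixed-type rule applies to columns the schema leaves untyped
  (wildcard or extra columns); columns with a declared scalar type
  already get precise per-cell `TYPE-MISMATCH` findings, and double
  reporting is avoided. Integer/decimal and date/datetime pairs widen
  rather than conflict.

Reports are sorted by (file, row, column, code), so two validations of
the same input are byte-identical in JSON — determinism is part of the
report contract, not an accident.

## Cross-domain formats

Dataset metadata is accepted as JSON (or the flat CSV template, via
the `dataset_metadata` schema); presence failures (title, abstract, at
least one creator) are errors, format failures (dates, coordinates)
are errors, and length shortfalls are warnings with configurable
minimums (title ≥ 40 characters, abstract ≥ 100 — attested checks
whose thresholds are a documented default here). JSON-LD export emits
a schema.org `Dataset` profile, refuses metadata with presence errors,
and is lossless: `import(export(md)) == md` on populated fields.

The file-level metadata (FLMD) table is itself validated under its own
schema before interpretation (the format family is self-hosting).
Its per-file missing-value codes feed the profiling of the files they
describe. Cross-file checks treat the FLMD as the bundle's table of
contents: rows naming absent files are errors, files without rows are
warnings, and the symmetric difference of (files on disk) and (files
listed) is exactly the set of `FILE-*` issues.

IGSN checking is syntactic only (no network): an optional `IGSN:`
prefix, a 2–5 letter namespace, then ≥ 4 alphanumerics,
case-insensitive with a normalization warning for lowercase. Note the
grammar is ambiguous for long letter runs (a 7-letter prefix parses as
5-letter namespace + code), which is inherent to the syntax, not a
defect of the checker.

Sample/location reference detection scans data tables only for the
harmonized identifier columns (`sample_id`, `parent_sample`,
`location_id`, `site_id`, `parent_location`) and only when the
corresponding registry table is part of the bundle — no heuristics on
arbitrary columns, no spurious errors for standalone tables.

Model archiving is a checklist, not a data dictionary: evaluation is
advisory (warnings with guidance for absent components,
`not_applicable` silent) and can never change a bundle's pass/fail
status.

## Domain formats

Domain validation always runs the base schema validation first, then
the format's own invariants, so it is a superset of the CSV checks.

- **Amplicon abundance**: count columns must be non-negative integers
  (`NEG-COUNT`, `COUNT-TYPE`), feature ids unique, sequences IUPAC DNA
  (ambiguity codes beyond `ACGTN` warn; anything else errors).
  Sequencing vs bioinformatic processing metadata travel as a
  two-block `(section, attribute, value)` file whose blocks must both
  be present and distinguished; representative sequences may instead
  be attached from a FASTA file keyed by `feature_id` (Biopython).
- **Water/soil chemistry**: below-detection results use the flag +
  detection-limit columns; `<value` strings embedded in the numeric
  cell are rejected with a fix-it message. The analyte vocabulary is
  deliberately extensible — closed vocabularies were explicitly
  rejected by the community this format serves — so unknown analytes
  warn and are collected as suggestions. Optional IGSNs are checked in
  place.
- **Time series**: out-of-order timestamps warn (field sensors get
  redeployed); duplicate timestamps within a hydrologic series error
  (they indicate merge faults). Soil respiration deliberately does
  *not* error on repeated timestamps because a multi-gas table
  legitimately repeats a chamber/timestamp across gas species.
- **Leaf gas exchange**: instrument-native headers are renamed onto
  the harmonized variables via the packaged translation table.

## Crosswalks

A crosswalk CSV has the fixed layout `target_format, source_standard,
source_term, target_term, unit_factor, unit_offset, notes`. Matching
is exact and case-sensitive by default (standards sometimes differ
only by case; silent folding could merge distinct terms), with an
explicit case-insensitive fallback. Unit conversion is affine only
(`harmonized = raw × factor + offset`) — enough for temperature,
length, and concentration scaling without an expression engine.
Translation renames mapped columns, converts declared units, preserves
unmapped columns verbatim (reported), refuses with `MAP-COLLISION`
when two source columns would land on one name, and is idempotent;
the loader refuses a non-identity conversion on a self-named term,
which is the one configuration that would break idempotence.

## The fixture generator

The generator emulates the *structure* the formats prescribe, not
scientific signal: no ecological covariance, no instrument physics.
Defaults are desk-scale — 20 rows per table, 5 samples, a one-degree
coordinate box near 37–38° N / 122–123° W, a 2021 growing-season date
range — chosen once as typical of a small field campaign's submission.
Sampling is documented and fully seeded: dates uniform in range,
coordinates uniform in the box, amplicon counts gamma-Poisson
(negative binomial, mean 25, dispersion 0.8 — overdispersion being the
one distributional fact about amplicon counts worth emulating),
sequences uniform over `ACGT`. The same spec and seed produce
byte-identical bundles.

Every bundle contains dataset metadata and an FLMD covering every
emitted file (itself included); each requested format adds its table.
With no violations requested the bundle validates with zero issues —
not merely zero errors — which makes fault-injection diffs exact.

Each of the 22 mutable issue codes has one fault generator that
perturbs a generated bundle and returns a ledger of exactly the issues
introduced. The central round-trip property — generate → mutate →
validate detects precisely the injected faults, no collateral — is
what the acceptance suite exercises for every code. Column-level
findings (mixed types) are ledgered at the header row. Mutators assume
the full default bundle; requesting a fault whose carrier file is not
in the bundle is an error, not a silent skip.

What passing these tests shows: the validator catches every rule
violation the catalogue names, at the right location, without false
positives *on well-formed structure*. What it does not show: behaviour
on the messiness of real submissions (exotic encodings, spreadsheet
artifacts, semantically wrong but well-formed values), which no
structural generator can certify.

## Numerical and degenerate-input choices

- Unit conversions format through `%.10g`, so inverse conversions
  round-trip within 1e-9 relative error.
- Coordinate and bounds checks are closed intervals; ties pass.
- Empty columns profile as `empty`, never mixed; a single non-missing
  cell cannot be mixed.
- Validation never raises on bad data — only structural failures
  (ragged rows, empty files, undecodable bytes, malformed schemas or
  crosswalks) raise, and each names its file and first violation.
- Exit codes: 0 pass, 1 validation failure at/above the threshold
  severity, 2 usage/I-O error.

## Problem sizes

The test suite and the acceptance script use the generator's default
sizes (20-row tables, 5 samples), 1000 randomized trials per oracle
comparison, and 100 tables for the idempotence checks; the whole suite
and the script each complete in seconds on one CPU.

## Known limitations

- Schemas ship the minimal defensible field core, not the full
  supplementary data dictionaries of each community format.
- No spreadsheet ingestion, no multi-gigabyte streaming, no sensor
  QA/QC (despiking, drift), no sequence processing, no IGSN network
  resolution, no repository upload.
- The FLMD role/schema auto-detection without a manifest is
  filename-heuristic and intended for interactive use; pipelines
  should carry the manifest.
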