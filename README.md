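# fairfmt

Schema-driven validation for community Earth- and environmental-science
(meta)data reporting formats.

Long-term data repositories receive heterogeneous CSV bundles — water
chemistry, sonde time series, amplicon count tables, leaf gas-exchange
records — each with its own column names, date conventions, and
missing-value habits. Community *reporting formats* fix that by
harmonizing terms and formats across data types: dates are always
`YYYY-MM-DD`, coordinates are always `latitude`/`longitude` in decimal
degrees within the closed bounds [−90, 90] and [−180, 180], missing
numeric values are `-9999`, and each data type gets a minimal set of
required fields so files stay programmatically parseable.

`fairfmt` encodes eleven such formats as machine-readable schemas —
six cross-domain (dataset metadata, file-level metadata, CSV
guidelines, sample IDs/IGSN, location metadata, terrestrial model
archiving) and five domain-specific (amplicon abundance tables,
leaf-level gas exchange, soil respiration, water and soil chemistry,
sonde-based hydrologic monitoring) — and provides:

- **bundle validation**: every file in a dataset bundle is checked
  under its schema, plus cross-file rules (file-level metadata
  coverage, sample/location referential integrity, IGSN syntax),
  producing a deterministic coded issue report;
- **format recommendation**: a decision workflow mapping what a
  dataset contains onto the formats that apply to it;
- **crosswalk translation**: tabular term crosswalks that rename
  external-standard headers (e.g. a water-quality standard's
  `ValueDateTime`) onto the harmonized vocabulary, with affine unit
  conversions, including a 10-instrument translation table for leaf
  gas-exchange output;
- **synthetic fixtures**: a seeded generator that emits valid bundles
  for any subset of the formats and can inject any catalogued fault
  exactly once, so every rule is testable offline.

It is aimed at data contributors checking their bundles before upload,
data managers curating submissions, and tool builders who need the
formats in machine-readable form.

## Worked example

Generate a synthetic bundle with one out-of-bounds latitude, then
validate it:

```sh
$ fairfmt generate-fixture -o demo --seed 5 -v COORD-RANGE
wrote 12 files + manifest to demo

$ fairfmt validate demo
ERROR   COORD-RANGE      locations.csv:3:latitude  latitude 95.0 outside [-90, 90]
1 issue(s): 1 error(s), 0 warning(s), 0 info. FAIL
```

The exit code is 1 (validation failure); 0 means pass and 2 means a
usage/I-O error. The single finding is the injected fault: row 3 of
`locations.csv` carries latitude 95.0, outside the closed bound of 90.
Re-running with `--output json` emits the same issues as a stable,
versioned JSON report.

Other verbs: `fairfmt describe <format-id|all>` renders a schema as a
field table, `fairfmt recommend --tabular --samples -t
water_soil_chemistry` walks the applicability workflow, and `fairfmt
translate --standard wqx --format hydrologic_monitoring file.csv`
renames foreign headers onto the harmonized terms.

The same operations are available as a library:

```python
from fairfmt import load_registry, load_bundle, validate_bundle

registry = load_registry()          # the 11 packaged schemas
report = validate_bundle(load_bundle("demo"), registry)
print(report.summary)               # {'error': 1, 'warning': 0, 'info': 0}
```

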