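id: file_level_metadata
title: File-level metadata (FLMD)
category: cross_domain
version: "1.1"
description: >
  One row per file in the dataset bundle, describing what each file
  contains, its format, and the missing-value codes its columns use.
applies_to: [tabular]
table_rules: [no-mixed-type-columns, iso-date-format]
fields:
  - name: file_name
    requirement: required
    value_type: identifier
    description: Exact name of the file within the bundle; unique per row.
  - name: file_description
    requirement: required
    value_type: text
  - name: file_format
    requirement: required
    value_type: text
    description: Format label, e.g. csv, json, fasta.
  - name: column_or_row_name_position
    requirement: optional
    value_type: integer
    description: 1-based position of the header row (or column) if not first.
  - name: missing_value_codes
    requirement: optional
    value_type: text
    description: Semicolon-separated missing codes used in this file, e.g. -9999;N/A.
  - name: notes
    requirement: optional
    value_type: text
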