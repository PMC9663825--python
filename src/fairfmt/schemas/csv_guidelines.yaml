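id: csv_guidelines
title: CSV file formatting guidelines
category: cross_domain
version: "1.1"
description: >
  Domain-agnostic rules for tabular files: RFC 4180 comma-separated text,
  a single header row of unique names (the wildcard field below matches
  any column), no mixed types within a column, dates as YYYY-MM-DD, and
  -9999 for missing numeric values.
applies_to: [tabular]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format]
fields:
  - name: "*"
    requirement: required
    value_type: text
    description: >
      Wildcard: the guidelines constrain how columns are formatted, not
      which columns exist. A table must have at least one named column.
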