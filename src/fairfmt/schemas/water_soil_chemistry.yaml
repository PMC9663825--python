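id: water_soil_chemistry
title: Sample-based water and soil chemistry
category: domain_specific
version: "1.1"
description: >
  Chemical concentration measurements on water, soil, and sediment
  samples. The analyte vocabulary is deliberately extensible: unknown
  analytes warn and are collected as suggestions, never rejected.
  Below-detection results use the flag + detection-limit columns, never
  '<value' inside the numeric cell.
applies_to: [water_soil_chemistry]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format,
              below-detection-flag, analyte-vocabulary]
fields:
  - name: sample_id
    requirement: required
    value_type: identifier
    description: Links to the sample metadata table when present.
  - name: igsn
    requirement: optional
    value_type: identifier
    description: IGSN of the sample, when registered.
  - name: analyte
    requirement: required
    value_type: text
    description: Measured analyte name (extensible vocabulary).
  - name: value
    requirement: required
    value_type: text
    description: Numeric result or a missing code; '<' strings are rejected.
  - name: unit
    requirement: required
    value_type: text
    description: Unit of the reported value, e.g. mg/L, ug/g.
  - name: method
    requirement: optional
    value_type: text
    description: Analytical method description or reference.
  - name: below_detection_flag
    requirement: optional
    value_type: controlled
    vocabulary: ["TRUE", "FALSE"]
  - name: detection_limit
    requirement: optional
    value_type: decimal
    description: Method detection limit, same unit as value.
  - name: matrix
    requirement: required
    value_type: controlled
    vocabulary: [water, soil, sediment]
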