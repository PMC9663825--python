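id: leaf_gas_exchange
title: Leaf-level gas exchange
category: domain_specific
version: "1.1"
description: >
  Harmonized variable names and units for leaf-level gas exchange
  measurements; instrument-native column names are renamed onto these via
  the packaged instrument translation table.
applies_to: [leaf_gas_exchange]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format]
fields:
  - name: record_id
    requirement: optional
    value_type: identifier
  - name: sample_id
    requirement: optional
    value_type: identifier
    description: Links to the sample metadata table when present.
  - name: A
    requirement: required
    value_type: decimal
    units: micromol CO2 m-2 s-1
    description: Net CO2 assimilation rate.
  - name: gsw
    requirement: required
    value_type: decimal
    units: mol H2O m-2 s-1
    description: Stomatal conductance to water vapour.
  - name: Ci
    requirement: optional
    value_type: decimal
    units: micromol mol-1
    description: Intercellular CO2 concentration.
  - name: Tleaf
    requirement: optional
    value_type: decimal
    units: deg C
    bounds: [-30, 60]
    description: Leaf temperature.
  - name: Qin
    requirement: optional
    value_type: decimal
    units: micromol m-2 s-1
    bounds: [0, 3000]
    description: Photosynthetically active radiation incident on the leaf.
  - name: instrument
    requirement: optional
    value_type: text
    description: Instrument token, resolvable in the translation table.
  - name: raw_or_processed
    requirement: optional
    value_type: controlled
    vocabulary: [raw, processed]
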