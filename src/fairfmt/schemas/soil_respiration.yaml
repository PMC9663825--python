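id: soil_respiration
title: Soil respiration
category: domain_specific
version: "1.1"
description: >
  Chamber-based soil-atmosphere gas exchange series covering greenhouse
  gases and radiocarbon, distinguished by a gas-species column rather
  than separate formats.
applies_to: [soil_respiration]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format,
              time-order]
fields:
  - name: timestamp
    requirement: required
    value_type: datetime
    description: ISO 8601 measurement timestamp (include a UTC offset).
  - name: chamber_id
    requirement: required
    value_type: identifier
    description: Chamber or collar identifier.
  - name: flux
    requirement: required
    value_type: decimal
    units: micromol m-2 s-1
    description: Soil-to-atmosphere gas flux (canonical unit; declare
      alternates via a crosswalk conversion).
  - name: gas_species
    requirement: required
    value_type: controlled
    vocabulary: [CO2, CH4, N2O, 14CO2]
  - name: soil_temperature
    requirement: optional
    value_type: decimal
    units: deg C
  - name: soil_moisture
    requirement: optional
    value_type: decimal
    units: m3 m-3
    bounds: [0, 1]
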