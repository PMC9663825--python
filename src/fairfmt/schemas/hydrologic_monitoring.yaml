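id: hydrologic_monitoring
title: Water level and sonde-based hydrologic monitoring
category: domain_specific
version: "1.1"
description: >
  Sonde time series harmonizing water level, temperature, and pH (plus
  extensible sensor variables) against a shared datetime column.
  Out-of-order timestamps warn (re-deployments happen); duplicates error.
applies_to: [hydrologic_monitoring]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format,
              time-order, time-dup]
fields:
  - name: datetime
    requirement: required
    value_type: datetime
    description: ISO 8601 observation timestamp (include a UTC offset).
  - name: site_id
    requirement: required
    value_type: identifier
    description: Monitoring site / sensor deployment identifier.
  - name: water_level
    requirement: optional
    value_type: decimal
    units: m
  - name: temperature
    requirement: optional
    value_type: decimal
    units: deg C
  - name: pH
    requirement: optional
    value_type: decimal
    units: pH units
    bounds: [0, 14]
  - name: notes
    requirement: optional
    value_type: text
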