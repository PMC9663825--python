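id: location_metadata
title: Location metadata
category: cross_domain
version: "1.1"
description: >
  Research locations with harmonized 'latitude'/'longitude' in decimal
  degrees (closed bounds -90..90 and -180..180).
applies_to: [locations]
table_rules: [no-mixed-type-columns, iso-date-format]
fields:
  - name: location_id
    requirement: required
    value_type: identifier
  - name: location_name
    requirement: optional
    value_type: text
  - name: latitude
    requirement: required
    value_type: latitude
    units: decimal degrees
  - name: longitude
    requirement: required
    value_type: longitude
    units: decimal degrees
  - name: elevation_m
    requirement: optional
    value_type: decimal
    units: m
    bounds: [-500, 9000]
    description: Elevation above mean sea level.
  - name: description
    requirement: optional
    value_type: text
  - name: parent_location
    requirement: optional
    value_type: identifier
    description: location_id of an enclosing site, if locations nest.
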