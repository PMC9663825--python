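id: sample_metadata
title: Sample IDs and metadata
category: cross_domain
version: "1.1"
description: >
  Registry of physical samples with globally resolvable identifiers
  (IGSN where possible) so samples can be tracked across labs, data
  systems, and collaborators.
applies_to: [samples]
table_rules: [no-mixed-type-columns, iso-date-format]
fields:
  - name: sample_id
    requirement: required
    value_type: identifier
    description: IGSN or locally unique sample identifier.
  - name: sample_name
    requirement: required
    value_type: text
  - name: material
    requirement: optional
    value_type: text
    description: Material sampled, e.g. soil, water, sediment, vegetation.
  - name: collection_date
    requirement: optional
    value_type: date
  - name: latitude
    requirement: optional
    value_type: latitude
    units: decimal degrees
  - name: longitude
    requirement: optional
    value_type: longitude
    units: decimal degrees
  - name: parent_sample
    requirement: optional
    value_type: identifier
    description: sample_id of the parent sample for subsamples.
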