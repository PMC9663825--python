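id: dataset_metadata
title: Dataset metadata
category: cross_domain
version: "1.1"
description: >
  Citation-grade metadata for a whole dataset: title, abstract, creators,
  keywords, and temporal/spatial coverage. Aligned with Ecological Metadata
  Language naming where fields overlap (e.g. 'title' is 'title').
applies_to: [any]
table_rules: [iso-date-format]
fields:
  - name: title
    requirement: required
    value_type: text
    description: Descriptive dataset title; aim for at least seven words.
  - name: abstract
    requirement: required
    value_type: text
    description: Abstract describing what, where, when, and how.
  - name: creator_name
    requirement: required
    value_type: text
    description: Name of a dataset creator (one row/entry per creator).
  - name: creator_affiliation
    requirement: optional
    value_type: text
  - name: creator_identifier
    requirement: optional
    value_type: identifier
    description: Researcher identifier such as an ORCID.
  - name: keywords
    requirement: optional
    value_type: text
    description: Semicolon-separated keyword list.
  - name: funding
    requirement: optional
    value_type: text
  - name: start_date
    requirement: optional
    value_type: date
    description: Start of temporal coverage, YYYY-MM-DD.
  - name: end_date
    requirement: optional
    value_type: date
    description: End of temporal coverage, YYYY-MM-DD.
  - name: latitude
    requirement: optional
    value_type: latitude
    units: decimal degrees
  - name: longitude
    requirement: optional
    value_type: longitude
    units: decimal degrees
  - name: related_identifiers
    requirement: optional
    value_type: text
    description: DOIs or other persistent identifiers of related resources.
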