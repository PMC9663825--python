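id: amplicon_abundance
title: Amplicon abundance tables
category: domain_specific
version: "1.1"
description: >
  Per-sample counts of marker-gene features with representative
  sequences. Columns beyond feature_id and representative_sequence are
  sample count columns of non-negative integers. Sequencing metadata and
  bioinformatic processing metadata accompany the table as a separate
  two-block methods file.
applies_to: [amplicon]
table_rules: [no-mixed-type-columns, missing-code-numeric, iso-date-format,
              count-columns-nonnegative, unique-feature-ids, sequence-alphabet]
fields:
  - name: feature_id
    requirement: required
    value_type: identifier
    description: OTU/ASV identifier, unique within the table.
  - name: representative_sequence
    requirement: required
    value_type: text
    description: >
      IUPAC DNA representative sequence (ACGTN; other ambiguity codes
      allowed with a warning). May alternatively be supplied as a FASTA
      file keyed by feature_id.
  - name: "*"
    requirement: optional
    value_type: text
    description: Sample count columns, one per sample, non-negative integers.
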