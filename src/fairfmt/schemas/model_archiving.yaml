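id: model_archiving
title: Terrestrial model data archiving
category: cross_domain
version: "1.1"
description: >
  Decision checklist for which components of a terrestrial model run to
  archive. Evaluated advisorily: absent components produce guidance, not
  failures.
applies_to: [model_output]
table_rules: []
fields:
  - name: item
    requirement: required
    value_type: controlled
    vocabulary: [model_code_version, inputs_forcings, configuration,
                 outputs, postprocessing_scripts, documentation]
    description: Archive component the row reports on.
  - name: status
    requirement: required
    value_type: controlled
    vocabulary: [present, absent, not_applicable]
  - name: evidence_file
    requirement: optional
    value_type: text
    description: Bundle file (or external reference) backing a 'present' status.
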