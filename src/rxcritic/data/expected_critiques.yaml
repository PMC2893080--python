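stage1_agi:
  conforms: false
  text: AGI should be prescribed only as second-line treatment. Guideline recommends
    metformin as first-line treatment.
stage1_metformin:
  conforms: true
  text: ''
stage1_other:
  conforms: false
  text: Sulfonamides, glinides and glitazones are not recommended. Guideline recommends
    metformin as first-line treatment.
stage2_agi:
  conforms: true
  text: ''
stage2_metformin:
  conforms: true
  text: ''
stage2_other:
  conforms: false
  text: Sulfonamides, glinides and glitazones are not recommended. Guideline recommends
    metformin as first-line treatment, and AGI as second-line.
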