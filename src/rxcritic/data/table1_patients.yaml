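stage1_metformin:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BA02
        inn: metformin
        dose:
          value: 850
          unit: mg
        form: tablet
stage1_agi:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BF01
        inn: acarbose
        dose:
          value: 300
          unit: mg
        form: tablet
stage1_other:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BB01
        inn: glibenclamide
        dose:
          value: 5
          unit: mg
        form: tablet
stage2_metformin:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BA02
        inn: metformin
        dose:
          value: 850
          unit: mg
        form: tablet
  history:
  - status: past
    efficacy: ineffective
    start: '2009-01-01'
    end: '2009-06-01'
    components:
    - non_drug: diet
    - drug:
        atc: A10BA02
        inn: metformin
        dose:
          value: 850
          unit: mg
        form: tablet
        tolerance: well_tolerated
stage2_agi:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BF01
        inn: acarbose
        dose:
          value: 300
          unit: mg
        form: tablet
  history:
  - status: past
    efficacy: ineffective
    start: '2009-01-01'
    end: '2009-06-01'
    components:
    - non_drug: diet
    - drug:
        atc: A10BA02
        inn: metformin
        dose:
          value: 850
          unit: mg
        form: tablet
        tolerance: well_tolerated
stage2_other:
  biological:
    HbA1c: 6.2
  critique_date: '2009-12-01'
  proposed:
    components:
    - non_drug: diet
    - drug:
        atc: A10BB01
        inn: glibenclamide
        dose:
          value: 5
          unit: mg
        form: tablet
  history:
  - status: past
    efficacy: ineffective
    start: '2009-01-01'
    end: '2009-06-01'
    components:
    - non_drug: diet
    - drug:
        atc: A10BA02
        inn: metformin
        dose:
          value: 850
          unit: mg
        form: tablet
        tolerance: well_tolerated
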