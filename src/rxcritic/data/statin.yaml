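name: dyslipaemia_statins
drug_classes:
  simvastatin:
  - C10AA01
  pravastatin:
  - C10AA03
  atorvastatin:
  - C10AA05
  rosuvastatin:
  - C10AA07
  statin:
  - C10AA
  fibrate:
  - C10AB
  lipid_lowering:
  - C10
attributes:
  age:
    type: number
    grid:
    - 75
    - 85
  prevention:
    type: string
    grid:
    - primary
    - secondary
recommendable_treatments:
- name: simvastatin
  components:
  - drug:
      atc: C10AA01
      inn: simvastatin
      dose:
        value: 20.0
        unit: mg
- name: pravastatin
  components:
  - drug:
      atc: C10AA03
      inn: pravastatin
      dose:
        value: 20.0
        unit: mg
- name: atorvastatin
  components:
  - drug:
      atc: C10AA05
      inn: atorvastatin
      dose:
        value: 10.0
        unit: mg
- name: rosuvastatin
  components:
  - drug:
      atc: C10AA07
      inn: rosuvastatin
      dose:
        value: 5.0
        unit: mg
recommendations:
- id: statin_lines
  type: should_prescribe
  conditions:
    not:
      and:
      - clinical:
        - age
        - '>'
        - 80
      - clinical:
        - prevention
        - '='
        - primary
  lines:
  - - components:
      - class: simvastatin
    - components:
      - class: pravastatin
    - components:
      - class: atorvastatin
  - - components:
      - class: rosuvastatin
  explanation_labels:
    2: Rosuvastatin should only be used in case of tolerance or efficacy problems
      with other statins.
    3: Only statins are recommended as first-line drug treatment.
  advice_labels:
    1: Guideline recommends simvastatin, pravastatin or atorvastatin as first-line
      treatment.
    2: Guideline recommends rosuvastatin as second-line treatment.
- id: no_treatment_over_80_primary
  type: should_not_prescribe
  conditions:
    and:
    - clinical:
      - age
      - '>'
      - 80
    - clinical:
      - prevention
      - '='
      - primary
  forbidden:
    components:
    - class: lipid_lowering
    - any
  criticism_label: It is not recommended to start a lipid-lowering treatment for patients
    older than 80, in primary prevention.
generic:
  applicability:
    1: not_applicable
    2: not_applicable
    3: not_applicable
    4: not_applicable
    5: full
    6: full
    7: full
    8: full
  exceptions:
    6:
    - fibrate
    - lipid_lowering
    - statin
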