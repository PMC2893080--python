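name: generic_exercise
drug_classes:
  nicotine_replacement:
  - N07BA01
  bupropion:
  - N06AX12
  beta_blocker:
  - C07A
  glinide:
  - A10BX02
  - A10BX03
  metformin:
  - A10BA02
recommendable_treatments:
- name: nicotine_patch
  components:
  - drug:
      atc: N07BA01
      inn: nicotine
      dose:
        value: 15.0
        unit: mg
      form: patch
- name: bupropion_150
  components:
  - drug:
      atc: N06AX12
      inn: bupropion
      dose:
        value: 150.0
        unit: mg
      form: tablet
recommendations:
- id: cessation_support
  type: should_prescribe
  lines:
  - - components:
      - class: nicotine_replacement
  - - components:
      - class: bupropion
  explanation_labels:
    2: Bupropion is a second-line aid.
    3: Other drugs are not recommended for smoking cessation.
  advice_labels:
    1: Guideline recommends nicotine replacement first.
    2: Guideline recommends nicotine replacement first, then bupropion.
generic:
  applicability:
    1: full
    2: full
    3: full
    4: full
    5: full
    6: full
    7: full
    8: full
  exceptions:
    4:
    - bupropion
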