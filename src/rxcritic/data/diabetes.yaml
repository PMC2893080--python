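name: diabetes_monotherapy
drug_classes:
  metformin:
  - A10BA02
  agi:
  - A10BF
  sulfonamide:
  - A10BB
  glinide:
  - A10BX02
  - A10BX03
  glitazone:
  - A10BG
  oral_antidiabetic:
  - A10B
non_drugs:
- diet
attributes:
  HbA1c:
    type: number
    grid:
    - 6.0
    - 7.0
recommendable_treatments:
- name: diet_metformin
  components:
  - non_drug: diet
  - drug:
      atc: A10BA02
      inn: metformin
      dose:
        value: 850.0
        unit: mg
      form: tablet
- name: diet_agi
  components:
  - non_drug: diet
  - drug:
      atc: A10BF01
      inn: acarbose
      dose:
        value: 300.0
        unit: mg
      form: tablet
recommendations:
- id: monotherapy_choice
  type: should_prescribe
  conditions:
    and:
    - therapeutic:
        scope: proposed
        pattern:
          components:
          - non_drug: diet
          - class: oral_antidiabetic
          cardinality: 1
    - clinical:
      - HbA1c
      - <=
      - 6.5
  lines:
  - - components:
      - non_drug: diet
      - class: metformin
  - - components:
      - non_drug: diet
      - class: agi
  explanation_labels:
    2: AGI should be prescribed only as second-line treatment.
    3: Sulfonamides, glinides and glitazones are not recommended.
  advice_labels:
    1: Guideline recommends metformin as first-line treatment.
    2: Guideline recommends metformin as first-line treatment, and AGI as second-line.
generic:
  applicability:
    1: not_applicable
    2: not_applicable
    3: not_applicable
    4: not_applicable
    5: not_applicable
    6: not_applicable
    7: not_applicable
    8: not_applicable
  exceptions:
    6:
    - oral_antidiabetic
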