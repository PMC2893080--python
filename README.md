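# rxcritic

Rule-based critiquing of physician drug prescriptions against clinical
practice guidelines (CPGs).

Most therapeutic recommendations in a CPG follow the pattern *"prescribe X
as first-line treatment, Y as second-line, ..."*. A critiquing decision
support system must turn such recommendations into executable **"if
conditions then criticism"** rules that fire when a prescription deviates
from the guideline, and must explain *why*: prescribing an alpha-glucosidase
inhibitor (AGI) to a treatment-naive diabetic patient and prescribing a
sulfonamide to the same patient both call for metformin instead, but for
different reasons, and the physician should be told the right one.

`rxcritic` is for medical-informatics developers building such systems: it
provides the knowledge representation (YAML knowledge bases), the compiler
that expands recommendations into rules, the inference engine that critiques
prescriptions against a patient's therapeutic history, and the verification
machinery that regenerates the encoded knowledge as a decision tree for
expert review.

## The model

A **knowledge base** holds drug classes (sets of hierarchical ATC codes; a
drug belongs to a class iff a class code is a prefix of its code),
**treatment patterns** — granularity-flexible queries over treatments
("any bitherapy", "metformin with poor tolerance", "a dose increase") —
and structured recommendations of three types, each expanded by the
compiler:

| type | generated rules |
|---|---|
| one should **not** prescribe | 1 |
| treatments of increasing power, N levels | N − 1 |
| one **should** prescribe, N lines | N(N + 1)/2 |

For a should-prescribe recommendation with N lines (line N+1 standing for
"any other treatment"), one rule is generated per pair (X, Y), 1 ≤ X ≤ N,
X+1 ≤ Y ≤ N+1:

> **if** (conditions) **and** (the patient is at the stage of line X)
> **and** (the proposed treatment is a treatment of line Y) **and** (it is
> not a treatment of a lower line) **then** criticize.

The patient is *at the stage of line X* when the treatments of lines below
X failed (were ineffective or poorly tolerated) and those of line X and
above did not. Each rule's criticism text is composed from the explanation
label of line Y, the advice label of line X and a bibliographic reference
label, so rules in the same column share their explanation and rules in the
same row share their advice.

Eight **generic recommendations** capture guideline-independent medical
common sense (continue an effective well-tolerated treatment; adjust doses
on inefficacy / excess effect / intolerance; do not represcribe what
recently failed; never two drugs of one class), with per-KB applicability
and exceptions (e.g. bupropion's dose cannot be lowered).

The engine critiques in four steps: fire all rules on the proposal;
concatenate the fired criticisms; build suggestions by substituting every
recommendable treatment and keeping those that fire nothing; and if no
suggestion survives, **relax** the line constraints step by step (accept a
second-line treatment for a first-line patient, then third-line, ...) until
a suggestion appears or the guideline is declared insufficient.

For quality assurance, the package enumerates all combinations of declared
attribute grids and history features, runs the engine on each input vector,
and induces an **unpruned C4.5-style decision tree** (0% training error)
from the (vector, output) pairs — a human-readable rewrite of the encoded
knowledge, ready to compare against the guideline text. A seeded test-base
generator produces, per patient profile, one conforming case per
recommended treatment plus five random non-recommended treatments that must
be criticized.

## Worked example

The shipped `diabetes.yaml` KB encodes: *for a monotherapy with
HbA1c ≤ 6.5%, prescribe metformin first-line and an AGI second-line.*
Critiquing an AGI prescription for a treatment-naive patient:

```sh
rxcritic critique src/rxcritic/data/diabetes.yaml patient.yaml
```

```
[default]
  criticism (monotherapy_choice:X1Y2): AGI should be prescribed only as second-line treatment. Guideline recommends metformin as first-line treatment.
  suggestions: diet_metformin
```

The exit code is 1 (criticized; 0 = conforms, 2 = insufficient guidance).
The rule id `X1Y2` says which of the three compiled rules fired: the
patient is at the stage of line 1, the proposal is a line-2 treatment.
Across the six possible (patient stage × proposal) situations of this
recommendation, exactly three are criticized, each with a different
composed text; `rxcritic compile src/rxcritic/data/diabetes.yaml` dumps all
three rules with their condition trees.

Other entry points: `rxcritic kb validate`, `rxcritic verify` (decision
tree), `rxcritic testgen` / `rxcritic run-tests`, `rxcritic match
--explain`, and `rxcritic fixtures [--regen]`. The same functionality is
available as a library (`rxcritic.critique`, `rxcritic.compile_kb`,
`rxcritic.induce_tree`, ...).

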