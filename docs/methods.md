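# Methods

## Knowledge representation

A knowledge base (KB) is a YAML document holding drug classes, recommendable
treatments, recommendations, and configuration for the eight generic
recommendations. The loader validates the whole document in one pass and
reports every violation with its location, so a KB author fixes a file in
one round trip rather than one error at a time. Loading, serializing and
re-loading a KB yields a structurally identical object (property-tested).

**ATC membership.** A drug belongs to a class iff one of the class's codes
is a prefix of the drug's full ATC code. The ATC nomenclature is
hierarchical, so this single rule lets classes sit at any level (`C07A` =
all beta blockers, `A10BA02` = metformin); classes that are not a single
subtree (the glinides) list several codes. Codes are validated against the
ATC level structure (letter, 2 digits, letter, letter, 2 digits, truncated
at any level).

**Treatment patterns** are queries, never concrete treatments. Matching a
treatment against a pattern requires an *injective* assignment of the
non-wildcard component slots onto distinct treatment components; the `Any`
wildcard absorbs leftovers within its repeat bounds. Injectivity is what
makes a two-slot same-class pattern mean "two distinct drugs of the class"
(the no-association generic). Cardinality constraints count drug components
only, so "diet + a single oral drug" is a monotherapy. Matching is
checked against a brute-force permutation matcher on randomized inputs.

**Missing data is fail-closed.** An absent attribute value, an `unknown`
tolerance or efficacy, or a dose in a different unit never satisfies a
constraint; each such decision leaves a note that surfaces in the critique
result. Dose comparison requires identical units and periods — no unit
conversion in this version; KB authors normalize. Rationale: a silent
mg/g conversion bug in a prescription critic is worse than a visible
"not comparable" note.

## Rule compilation

The three recommendation types expand to 1, N−1 and N(N+1)/2 rules
respectively (checked as closed forms over randomized N). Two decisions
deserve explanation:

* **Stage clauses.** "The patient is at the stage of line X" is: X=1 — no
  failed (ineffective or poorly tolerated, after outcome normalization)
  treatment of any line in the history; 1<X<N — no failed treatment of
  line ≥ X and a failed one of line X−1; X=N — a failed treatment of line
  N−1 or N. For N ≥ 2 these clauses partition all histories
  (property-tested). For N = 1 the first clause is also the last: a patient
  whose single recommended line already failed satisfies *no* stage, the
  recommendation goes silent, and represcription policing falls to generics
  #5/#6. This edge is deliberate — inventing a stage for an exhausted
  single-line recommendation would re-advise the treatment that failed.
* **Increasing power.** Power levels are ordered from least to most
  powerful; one rule is generated per level X below the top: *proposed is a
  level-X treatment and some level Y > X was ineffective in the history* —
  prescribing a weaker treatment than one that already failed. This yields
  exactly N−1 rules and makes the fibrate-after-failed-statin case fire.

Criticism texts are composed at compile time (explanation label of the
proposed line + advice label of the patient's stage + reference label), so
the engine only concatenates; exact duplicate texts across fired rules are
emitted once.

**Generic recommendations.** #1 compiles to one rule (stable current
treatment + any change proposed), #2–4 to one rule each (dose moves against
inefficacy / excess effect / intolerance), #5 to one rule per recommendable
treatment ("ineffective within the last three years and stopped — i.e. not
followed by another course of the same treatment"), #6 and #8 to one rule
per drug class. #7 (a treatment both ineffective and poorly tolerated is
handled through the poor-tolerance pathway) compiles to **no rule**: it is
realized by outcome normalization, which masks the efficacy of dual-failure
treatments for matching while leaving the stored efficacy and all tolerance
values intact. Exceptions remove an entity from its per-entity rule or add
a "proposal does not contain the excepted class" conjunct to a singleton
rule; partial applicability restricts a rule to a configured class subset.

Parameters: the "recent past" window of generic #5 is 3 years (1095 days),
measured from the past treatment's end date to the critique date — the
guideline gives the bound, the anchor is our choice. Treatment identity for
#5/#6 ("the same treatment T") is at INN granularity: doses and forms are
not compared, since a represcription at another dose is still a
represcription.

## Engine

Step 1 evaluates every rule on the proposal (verdict always at strict
level k = 0); step 2 composes the text; step 3 substitutes each
recommendable treatment for the proposal (recomputing its relative-posology
flags against the current treatment) and keeps those that fire nothing;
step 4 relaxes: at level k every should-prescribe rule with line gap
Y − X ≤ k is suppressed and step 3 re-runs, up to k = N−1. Line-N+1 ("any
other treatment") rules and all generic/should-not rules are never
suppressed, so a non-recommended or failed treatment can never become a
suggestion. Relaxation widens the *suggestion search only*; the proposal's
verdict is not softened — the system relaxes to find something to propose,
not to excuse the prescription. The returned level is minimal and the
suggestion set is non-shrinking in k (property-tested), and the whole
result is deterministic byte-for-byte.

Multi-indication prescriptions are regrouped by the KB's (drug class, dose
range) → indication map — dose-dependent for drugs like aspirin, with
duplication when a drug serves several indications — and each group is
critiqued independently. With no map the proposal forms a single group.

## Verification

Input vectors are the cartesian product of the declared attribute grids and
categorical history features. The default history encoder exposes one
feature per recommendable treatment with values none / ineffective /
poorly_tolerated; "poorly tolerated" also appends a later drug-free entry
so the "was stopped" clause of generic #6 is observable. The encoder is
replaceable — real histories are richer than any fixed encoding.

The engine's output for a vector is encoded as one categorical label:
accepted treatments in KB order, bracketed when accepted only under
relaxation (second-line only), `no treatment` when nothing is ever
accepted. Tree induction is C4.5-style: multiway splits on the attribute
with the best gain ratio (among those with positive gain), ties broken by
feature declaration order, recursion to label-pure leaves, **pruning
disabled** so training error is 0% by construction; fidelity (tree output =
engine output on 100% of vectors) is asserted, not assumed. An enumeration
cap (default 100 000 vectors) refuses KBs whose tree would not be
human-readable.

Test bases contain, per patient profile, one positive case per treatment
the engine recommends for that profile (checked at that treatment's minimal
relaxation level) and up to five seeded-random negatives drawn from
(non-recommended class, KB dose grid) pairs. Negatives are verified
criticized at generation time: where the guideline does not constrain a
profile at all, no criticized negative exists and the base carries an
explicit warning instead of a vacuous case.

## Fixtures: what they emulate, and what they do not

The three toy KBs (diabetes monotherapy, a statin/dyslipaemia fragment, a
smoking-cessation generic exerciser) reconstruct the published worked
examples: the six-cell critique matrix with its exact texts, the
over-80-primary-prevention "no treatment" path with rosuvastatin bracketed
as second-line, and the bupropion dose exception. Critique expectations are
regenerated through the engine (`rxcritic fixtures --regen`), never
hand-edited; a test fails if the committed files drift.

The fixture KBs declare umbrella classes (`oral_antidiabetic`, `statin`,
`lipid_lowering`) for pattern granularity but exempt them from generic #6:
one drug's intolerance should not forbid its whole therapeutic family.
This is a KB-authoring decision the exceptions mechanism exists for.

Passing on these KBs shows the compiler, engine and verifier are faithful
to the model — not that the model covers a full national guideline: the
toys have 1–2 recommendations each, single-indication maps, no treatment
durations and no EPR integration, and the randomized KBs used in property
tests are single-pattern-per-line should-prescribe structures. Scaling
numbers (rule and pattern counts of full guideline KBs, response times)
are out of scope.

## Known limitations

* No dose-unit conversion; no fuzzy matching; no drug-interaction checking
  (the province of separate reminder systems).
* Efficacy/tolerance are inputs (in a deployed system the physician supplies
  them through the record); `too_effective` is likewise supplied, not
  derived from lab values.
* A pattern without a status constraint matches past, current and proposed
  treatments alike; KB authors constrain status where it matters.
* Suggestion order is KB declaration order — no clinical ranking.
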