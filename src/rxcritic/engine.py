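"""The inference engine: fire rules, compose the critique, suggest, relax.

Most of the reasoning lives in the compiled rules; the engine itself
performs four steps:

1. evaluate every rule against the physician's proposed treatment — any
   firing rule makes the prescription non-conforming;
2. compose the textual criticism by concatenating the texts of the fired
   rules (exact duplicates are emitted once);
3. build the suggestion list by substituting each recommendable treatment
   of the guideline for the proposal and retaining those that fire no
   rule;
4. if no suggestion survives, *relax* the rules — at level k every
   should_prescribe-derived rule with line gap Y − X ≤ k is suppressed, so
   a second-line treatment becomes acceptable for a stage-one patient —
   and retry step 3, up to k = N−1.  If the list is still empty the
   guideline does not provide enough information for this patient
   (everything is contraindicated, poorly tolerated or ineffective).

The proposal's verdict is always reported strictly (k = 0); relaxation
only widens the suggestion search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .kb_model import KnowledgeBase
from .matching import MatchContext, eval_condition
from .patient_model import (
    PatientRecord,
    Treatment,
    assign_indications,
    enrich,
    normalize_outcomes,
    treatment_from_template,
)
from .rule_compiler import CritiqueRule, RuleSet, compile_kb

__all__ = [
    "CritiqueResult",
    "FiredRule",
    "critique",
    "critique_by_indication",
    "suggest",
    "compose_text",
    "suggestion_min_k",
    "prepare_record",
]


@dataclass(frozen=True)
class FiredRule:
    rule_id: str
    text: str


@dataclass
class CritiqueResult:
    """Outcome of one critique run (one indication group).

    Invariants: ``conforms`` iff ``criticisms`` is empty;
    ``insufficient_guidance`` implies the suggestion list stayed empty at
    maximal relaxation.  ``relaxation_level`` is the smallest k at which a
    suggestion survived (0 when the strict rules already admit one).
    """

    conforms: bool
    criticisms: list[FiredRule] = field(default_factory=list)
    composed_text: str = ""
    suggestions: list[str] = field(default_factory=list)
    relaxation_level: int = 0
    insufficient_guidance: bool = False
    missing_data_notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "conforms": self.conforms,
            "criticisms": [{"rule": f.rule_id, "text": f.text}
                           for f in self.criticisms],
            "composed_text": self.composed_text,
            "suggestions": list(self.suggestions),
            "relaxation_level": self.relaxation_level,
            "insufficient_guidance": self.insufficient_guidance,
            "missing_data_notes": list(self.missing_data_notes),
        }


def prepare_record(record: PatientRecord, kb: KnowledgeBase) -> PatientRecord:
    """Outcome normalization then data enriching, in that order (the
    enriched change flags must see the record the matcher will see)."""
    return enrich(normalize_outcomes(record), kb)


def _fired(ruleset: RuleSet, record: PatientRecord, kb: KnowledgeBase,
           k: int, notes: Optional[list[str]] = None) -> list[CritiqueRule]:
    ctx = MatchContext(record=record, kb=kb)
    out = [r for r in ruleset.active_rules(k) if eval_condition(r.condition, ctx)]
    if notes is not None:
        notes.extend(n for n in ctx.notes if n not in notes)
    return out


def _with_proposal(record: PatientRecord, kb: KnowledgeBase,
                   candidate: Treatment) -> PatientRecord:
    sub = PatientRecord(clinical=record.clinical, biological=record.biological,
                        history=record.history, proposed=candidate,
                        critique_date=record.critique_date)
    return prepare_record(sub, kb)


def suggest(record: PatientRecord, kb: KnowledgeBase, ruleset: RuleSet,
            k: int = 0) -> list[str]:
    """Names of the recommendable treatments that, substituted for the
    proposal, trigger no rule at relaxation level k.  Order follows the
    KB's declaration order."""
    out = []
    for template in kb.recommendable_treatments:
        candidate = treatment_from_template(template)
        sub = _with_proposal(record, kb, candidate)
        if not _fired(ruleset, sub, kb, k):
            out.append(template.name)
    return out


def compose_text(fired: list[CritiqueRule | FiredRule]) -> str:
    """Concatenate fired-rule texts in rule order, one per line; exact
    duplicate texts (rules sharing a composed label) are emitted once."""
    seen: list[str] = []
    for f in fired:
        text = f.criticism if isinstance(f, CritiqueRule) else f.text
        if text and text not in seen:
            seen.append(text)
    return "\n".join(seen)


def critique(record: PatientRecord, kb: KnowledgeBase,
             ruleset: Optional[RuleSet] = None,
             prepared: bool = False) -> CritiqueResult:
    """Run the four-step critique for one proposal (one indication group)."""
    if record.proposed is None:
        raise ValueError("critique needs exactly one proposed treatment")
    if ruleset is None:
        ruleset = compile_kb(kb)
    if not prepared:
        record = prepare_record(record, kb)
    notes = [n for n in record.notes if n.startswith("enrich:")]

    fired = _fired(ruleset, record, kb, k=0, notes=notes)
    result = CritiqueResult(conforms=not fired,
                            criticisms=[FiredRule(r.id, r.criticism)
                                        for r in fired],
                            composed_text=compose_text(fired),
                            missing_data_notes=notes)
    for k in range(ruleset.k_max + 1):
        suggestions = suggest(record, kb, ruleset, k)
        if suggestions:
            result.suggestions = suggestions
            result.relaxation_level = k
            return result
    result.relaxation_level = ruleset.k_max
    result.insufficient_guidance = True
    return result


def critique_by_indication(record: PatientRecord, kb: KnowledgeBase,
                           ruleset: Optional[RuleSet] = None
                           ) -> dict[str, CritiqueResult]:
    """Regroup the proposed drugs by indication and critique each group.

    Returns indication -> result; unmapped drugs are reported through a
    note on every result rather than silently ignored.
    """
    if ruleset is None:
        ruleset = compile_kb(kb)
    prepared = prepare_record(record, kb)
    groups = assign_indications(prepared, kb)
    results: dict[str, CritiqueResult] = {}
    for indication, sub_prescription in groups.items():
        sub = PatientRecord(clinical=prepared.clinical,
                            biological=prepared.biological,
                            history=prepared.history,
                            proposed=sub_prescription,
                            critique_date=prepared.critique_date,
                            notes=list(prepared.notes))
        results[indication] = critique(sub, kb, ruleset, prepared=True)
    for res in results.values():
        for name in groups.unmapped:
            res.missing_data_notes.append(f"unmapped drug: {name}")
    return results


def suggestion_min_k(record: PatientRecord, kb: KnowledgeBase,
                     ruleset: Optional[RuleSet] = None,
                     prepared: bool = False) -> dict[str, Optional[int]]:
    """For each recommendable treatment, the smallest relaxation level at
    which it conforms for this patient (None if it never does).  This is
    the label the verification decision tree is trained on: level 0 plain,
    higher levels rendered in brackets ("second-line only")."""
    if ruleset is None:
        ruleset = compile_kb(kb)
    if not prepared:
        record = prepare_record(record, kb)
    out: dict[str, Optional[int]] = {}
    for template in kb.recommendable_treatments:
        sub = _with_proposal(record, kb, treatment_from_template(template))
        out[template.name] = None
        for k in range(ruleset.k_max + 1):
            if not _fired(ruleset, sub, kb, k):
                out[template.name] = k
                break
    return out
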