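"""Compilation of recommendations into "if conditions then criticism" rules.

This module houses the system's central algorithms.  Each structured
recommendation is expanded into executable rules whose conditions combine
the recommendation's own conditions with *stage* and *line* tests:

* ``should_not_prescribe`` — one rule: conditions AND the proposal matches
  the forbidden pattern.
* ``increasing_power`` (N power levels) — N−1 rules, one per level X below
  the top: conditions AND the proposal is a level-X treatment AND some more
  powerful level was ineffective in the history (prescribing a weaker
  treatment than one that already failed).
* ``should_prescribe`` (N lines, line N+1 standing for any other
  treatment) — N(N+1)/2 rules, one per pair (X, Y) with 1 ≤ X ≤ N and
  X+1 ≤ Y ≤ N+1: conditions AND the patient is at the stage of line X AND
  the proposal is a line-Y treatment AND not a treatment of a lower line
  (lines may overlap: "simvastatin as first-line, any statin as
  second-line").  The rule's criticism is composed at compile time from
  the explanation label of line Y, the advice label of line X and the
  reference label.

The patient is at the stage of line X iff: X=1 — no failed (ineffective or
poorly tolerated) treatment of any line in the history; 1<X<N — no failed
treatment of line ≥ X and a failed one of line X−1; X=N — a failed
treatment of line N−1 or N.  These clauses partition the histories whose
failures all fall on the recommendation's own lines.

The eight generic recommendations compile per the configured
applicability: #1 one rule, #2–4 three rules, #5 one rule per
recommendable treatment, #6 and #8 one rule per drug class; #7 produces no
rule at all — it is realized by outcome normalization before matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

from .kb_model import (
    AND,
    ANY,
    NATIVE,
    NOT,
    OR,
    THER,
    ComponentPattern,
    Cond,
    GenericRecConfig,
    KnowledgeBase,
    Recommendation,
    TreatmentPattern,
    cond_to_dict,
)

__all__ = [
    "CritiqueRule",
    "RuleSet",
    "CompileError",
    "stage_condition",
    "compile_should_prescribe",
    "compile_should_not_prescribe",
    "compile_increasing_power",
    "compile_generic",
    "compile_kb",
    "GENERIC_DEFAULT_LABELS",
    "RECENT_PAST_DAYS",
]

#: "Recent past" window for generic #5: a treatment ineffective more than
#: three years ago may work again if the patient's condition has changed.
RECENT_PAST_DAYS = 3 * 365

GENERIC_DEFAULT_LABELS = {
    1: "The current treatment is effective and well tolerated; "
       "it should be continued unchanged.",
    2: "The current treatment is ineffective but well tolerated; "
       "the dose can be increased, not reduced.",
    3: "The current treatment is too effective; "
       "the dose should be decreased, not increased.",
    4: "A drug of the current treatment is poorly tolerated; "
       "its dose should be decreased, not increased.",
    5: "{name} was ineffective in the recent past; "
       "it should not be prescribed again.",
    6: "A drug of the class {name} was poorly tolerated in the past; "
       "drugs of this class should not be prescribed again.",
    8: "Two drugs of the class {name} should not be prescribed "
       "in association.",
}


class CompileError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("compilation failed:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


@dataclass(frozen=True)
class CritiqueRule:
    """One executable rule: condition tree, composed criticism text, and
    provenance (source recommendation or generic id, the (X, Y) pair for
    should_prescribe-derived rules).  Only should_prescribe rules with a
    finite line gap are *relaxable*: at relaxation level k every rule with
    Y − X ≤ k is suppressed, so a line-(X+1) treatment becomes acceptable
    for a stage-X patient; "any other treatment" rules (Y = N+1) are never
    suppressed."""

    id: str
    condition: Cond
    criticism: str
    source: str
    X: Optional[int] = None
    Y: Optional[int] = None
    relaxable: bool = False

    def suppressed_at(self, k: int) -> bool:
        return (self.relaxable and self.X is not None and self.Y is not None
                and (self.Y - self.X) <= k)

    def to_dict(self) -> dict:
        d: dict = {"id": self.id, "source": self.source}
        if self.X is not None:
            d["X"] = self.X
        if self.Y is not None:
            d["Y"] = self.Y
        d["relaxable"] = self.relaxable
        d["criticism"] = self.criticism
        d["condition"] = cond_to_dict(self.condition)
        return d


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[CritiqueRule, ...]
    kb: KnowledgeBase

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def k_max(self) -> int:
        """Maximal relaxation level: max over should_prescribe
        recommendations of N − 1 (0 when none)."""
        ns = [r.n_lines for r in self.kb.recommendations
              if r.rec_type == "should_prescribe"]
        return max((n - 1 for n in ns), default=0)

    def active_rules(self, k: int = 0) -> list[CritiqueRule]:
        return [r for r in self.rules if not r.suppressed_at(k)]

    def to_json(self) -> str:
        """Deterministic audit dump: same KB, byte-identical output."""
        return json.dumps([r.to_dict() for r in self.rules],
                          indent=2, ensure_ascii=False)


# --------------------------------------------------------------------------
# Helper condition builders
# --------------------------------------------------------------------------

def _any_pat(**kw) -> TreatmentPattern:
    return TreatmentPattern(components=(ANY,), **kw)


def _class_comp(name: str) -> ComponentPattern:
    return ComponentPattern(kind="drug_class_ref", drug_class=name)


def _proposed_is_line(rec: Recommendation, y: int) -> Cond:
    """"The proposed treatment is a treatment of line Y"; line N+1 means it
    matches no pattern of any explicit line."""
    n = rec.n_lines
    if y <= n:
        return OR(*[THER(p, scope="proposed") for p in rec.lines[y - 1]])
    return NOT(OR(*[THER(p, scope="proposed")
                    for line in rec.lines for p in line]))


def _failed_line(rec: Recommendation, line: int) -> Cond:
    """"There is a failed (ineffective or poorly tolerated) treatment of
    this line in the therapeutic history"."""
    return OR(*[THER(replace(p, failed=True), scope="history")
                for p in rec.lines[line - 1]])


def stage_condition(rec: Recommendation, x: int) -> Cond:
    """Condition for "the patient is at the stage of line X"."""
    n = rec.n_lines
    if not 1 <= x <= n:
        raise ValueError(f"stage {x} out of range 1..{n}")
    if x == 1:
        return AND(*[NOT(_failed_line(rec, line)) for line in range(1, n + 1)])
    if x == n:
        return OR(_failed_line(rec, n - 1), _failed_line(rec, n))
    return AND(*([NOT(_failed_line(rec, line)) for line in range(x, n + 1)]
                 + [_failed_line(rec, x - 1)]))


# --------------------------------------------------------------------------
# Per-type compilation
# --------------------------------------------------------------------------

def compile_should_not_prescribe(rec: Recommendation) -> list[CritiqueRule]:
    if rec.rec_type != "should_not_prescribe":
        raise CompileError([f"{rec.id}: not a should_not_prescribe recommendation"])
    if rec.forbidden is None:
        raise CompileError([f"{rec.id}: missing forbidden pattern"])
    cond = AND(rec.conditions, THER(rec.forbidden, scope="proposed"))
    return [CritiqueRule(id=f"{rec.id}", condition=cond,
                         criticism=_join(rec.criticism_label, "",
                                         rec.reference_label),
                         source=rec.id)]


def compile_increasing_power(rec: Recommendation) -> list[CritiqueRule]:
    if rec.rec_type != "increasing_power":
        raise CompileError([f"{rec.id}: not an increasing_power recommendation"])
    n = rec.n_lines
    if n < 2:
        raise CompileError([f"{rec.id}: increasing_power needs N >= 2 levels"])
    rules = []
    for x in range(1, n):  # each level below the top: N - 1 rules
        stronger_failed = OR(*[
            THER(replace(p, efficacy="ineffective"), scope="history")
            for y in range(x + 1, n + 1) for p in rec.lines[y - 1]])
        cond = AND(rec.conditions, _proposed_is_line(rec, x), stronger_failed)
        rules.append(CritiqueRule(
            id=f"{rec.id}:P{x}", condition=cond,
            criticism=_join(rec.criticism_label, "", rec.reference_label),
            source=rec.id, X=x))
    return rules


def _join(*parts: str) -> str:
    return " ".join(p for p in parts if p)


def compile_should_prescribe(rec: Recommendation) -> list[CritiqueRule]:
    if rec.rec_type != "should_prescribe":
        raise CompileError([f"{rec.id}: not a should_prescribe recommendation"])
    n = rec.n_lines
    errors = [f"{rec.id}: missing advice label for line {x}"
              for x in range(1, n + 1) if not rec.advice_labels.get(x)]
    errors += [f"{rec.id}: missing explanation label for line {y}"
               for y in range(2, n + 2) if not rec.explanation_labels.get(y)]
    if errors:
        raise CompileError(errors)
    rules = []
    for x in range(1, n + 1):
        for y in range(x + 1, n + 2):
            parts = [rec.conditions, stage_condition(rec, x),
                     _proposed_is_line(rec, y)]
            if y <= n:
                # lines can overlap; a line-<Y match takes precedence
                parts += [NOT(_proposed_is_line(rec, j)) for j in range(1, y)]
            rules.append(CritiqueRule(
                id=f"{rec.id}:X{x}Y{y}", condition=AND(*parts),
                criticism=_join(rec.explanation_labels[y],
                                rec.advice_labels[x], rec.reference_label),
                source=rec.id, X=x, Y=y, relaxable=(y <= n)))
    assert len(rules) == n * (n + 1) // 2
    return rules


# --------------------------------------------------------------------------
# Generic recommendations
# --------------------------------------------------------------------------

def _generic_label(kb: KnowledgeBase, gid: int, name: str = "") -> str:
    tpl = kb.generic.labels.get(gid, GENERIC_DEFAULT_LABELS[gid])
    return tpl.format(name=name)


def _class_exclusions(kb: KnowledgeBase, gid: int) -> list[Cond]:
    """NOT(proposal contains a drug of the excepted class), per exception."""
    out = []
    for name in sorted(kb.generic.exceptions.get(gid, ())):
        if name in kb.drug_classes:
            out.append(NOT(THER(TreatmentPattern(
                components=(_class_comp(name), ANY)), scope="proposed")))
    return out


def _partial_scope(kb: KnowledgeBase, gid: int) -> list[Cond]:
    """Partial applicability: the rule only concerns proposals touching the
    configured drug-class subset."""
    if kb.generic.applies(gid) != "partial":
        return []
    names = sorted(n for n in kb.generic.restrict_to.get(gid, ())
                   if n in kb.drug_classes)
    if not names:
        return []
    return [OR(*[THER(TreatmentPattern(components=(_class_comp(n), ANY)),
                      scope="proposed") for n in names])]


def _entity_scope(kb: KnowledgeBase, gid: int, names: list[str]) -> list[str]:
    """Entity list for per-treatment/per-class generics, after exceptions
    and partial restriction."""
    exc = kb.generic.exceptions.get(gid, frozenset())
    names = [n for n in names if n not in exc]
    if kb.generic.applies(gid) == "partial":
        restrict = kb.generic.restrict_to.get(gid)
        if restrict:
            names = [n for n in names if n in restrict]
    return names


def compile_generic(kb: KnowledgeBase) -> list[CritiqueRule]:
    cfg: GenericRecConfig = kb.generic
    rules: list[CritiqueRule] = []

    def on(gid: int) -> bool:
        return cfg.applies(gid) != "not_applicable"

    if on(1):
        cond = AND(NATIVE("current_conforms_effective_well_tolerated"),
                   THER(_any_pat(changes=frozenset(
                       ("inn_change", "dose_increase", "dose_decrease",
                        "form_change"))), scope="proposed"),
                   *_class_exclusions(kb, 1), *_partial_scope(kb, 1))
        rules.append(CritiqueRule(id="generic#1", condition=cond,
                                  criticism=_generic_label(kb, 1),
                                  source="generic#1"))
    # Dose-related generic recommendations (#2, #3, #4): three rules.
    dose_block = (
        (2, _any_pat(status="current", efficacy="ineffective",
                     overall_tolerance="well_tolerated"), "dose_decrease"),
        (3, _any_pat(status="current", efficacy="too_effective"),
         "dose_increase"),
        (4, _any_pat(status="current", overall_tolerance="poorly_tolerated"),
         "dose_increase"),
    )
    for gid, current_pat, change in dose_block:
        if not on(gid):
            continue
        cond = AND(THER(current_pat, scope="history"),
                   THER(_any_pat(changes=frozenset((change,))),
                        scope="proposed"),
                   *_class_exclusions(kb, gid), *_partial_scope(kb, gid))
        rules.append(CritiqueRule(id=f"generic#{gid}", condition=cond,
                                  criticism=_generic_label(kb, gid),
                                  source=f"generic#{gid}"))
    if on(5):
        for name in _entity_scope(kb, 5, [t.name for t in
                                          kb.recommendable_treatments]):
            cond = NATIVE("represcribed_ineffective_treatment",
                          treatment=name, window_days=RECENT_PAST_DAYS)
            rules.append(CritiqueRule(
                id=f"generic#5:{name}", condition=cond,
                criticism=_generic_label(kb, 5, name), source="generic#5"))
    if on(6):
        for name in _entity_scope(kb, 6, list(kb.drug_classes)):
            cond = NATIVE("represcribed_poorly_tolerated_class",
                          drug_class=name)
            rules.append(CritiqueRule(
                id=f"generic#6:{name}", condition=cond,
                criticism=_generic_label(kb, 6, name), source="generic#6"))
    # #7 compiles to no rule: it is enforced by outcome normalization.
    if on(8):
        for name in _entity_scope(kb, 8, list(kb.drug_classes)):
            # two slots of the same class + injective matching = two
            # distinct drugs of the class in the proposal
            pat = TreatmentPattern(components=(_class_comp(name),
                                               _class_comp(name), ANY))
            rules.append(CritiqueRule(
                id=f"generic#8:{name}", condition=THER(pat, scope="proposed"),
                criticism=_generic_label(kb, 8, name), source="generic#8"))
    return rules


# --------------------------------------------------------------------------
# Whole-KB compilation
# --------------------------------------------------------------------------

_COMPILERS = {
    "should_prescribe": compile_should_prescribe,
    "should_not_prescribe": compile_should_not_prescribe,
    "increasing_power": compile_increasing_power,
}


def compile_kb(kb: KnowledgeBase) -> RuleSet:
    """Compile every recommendation plus the generic recommendations.

    Deterministic order: recommendations in declaration order (with (X, Y)
    lexicographic inside a should_prescribe expansion), then generic rules
    by id and entity declaration order.  Compilation is pure: the same KB
    yields a byte-identical audit dump.
    """
    rules: list[CritiqueRule] = []
    errors: list[str] = []
    for rec in kb.recommendations:
        try:
            rules.extend(_COMPILERS[rec.rec_type](rec))
        except CompileError as e:
            errors.extend(e.errors)
    if errors:
        raise CompileError(errors)
    rules.extend(compile_generic(kb))
    return RuleSet(rules=tuple(rules), kb=kb)
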