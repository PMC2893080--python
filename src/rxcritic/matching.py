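"""Evaluation of predicates, treatment patterns and condition expressions.

A treatment pattern is a query read as "there exists in the therapeutic
history at least one treatment matching the pattern".  Matching a single
treatment against a pattern requires an *injective* assignment of the
pattern's non-wildcard component slots onto distinct treatment components
(one real component cannot satisfy two slots — this is what lets a pattern
with two slots of the same class demand two distinct drugs of that class);
the ``Any`` wildcard absorbs the leftover components within its repeat
bounds.

Missing data is fail-closed throughout: an absent attribute value, an
unknown tolerance or efficacy, or a dose in a different unit never
satisfies a constraint; a note is accumulated in the match context so the
critique can surface what was missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

from .kb_model import (
    ClinicalPredicate,
    ComponentPattern,
    Cond,
    DrugClass,
    KnowledgeBase,
    NonDrug,
    TreatmentPattern,
    TreatmentTemplate,
)
from .patient_model import DrugLine, PatientRecord, Treatment

__all__ = [
    "MatchContext",
    "MatchEvalError",
    "eval_predicate",
    "match_component",
    "match_treatment",
    "history_exists",
    "eval_condition",
    "treatment_matches_template",
]


class MatchEvalError(ValueError):
    """A condition references an attribute with an incompatible value type."""


@dataclass
class MatchContext:
    """Everything a condition needs: the enriched record and the KB.

    ``notes`` accumulates missing-data diagnostics (fail-closed decisions)
    for display alongside the critique.
    """

    record: PatientRecord
    kb: KnowledgeBase
    notes: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        if msg not in self.notes:
            self.notes.append(msg)


# --------------------------------------------------------------------------
# Clinical predicates
# --------------------------------------------------------------------------

_NUMERIC_OPS = ("<", "<=", ">", ">=")


def eval_predicate(p: ClinicalPredicate, ctx: MatchContext) -> bool:
    value = ctx.record.attribute(p.attribute)
    if value is None:
        ctx.note(f"missing data: {p.attribute}")
        return False
    if p.op in _NUMERIC_OPS:
        try:
            v, ref = float(value), float(p.value)
        except (TypeError, ValueError):
            raise MatchEvalError(
                f"attribute {p.attribute!r}: non-numeric comparison "
                f"{value!r} {p.op} {p.value!r}") from None
        return {"<": v < ref, "<=": v <= ref,
                ">": v > ref, ">=": v >= ref}[p.op]
    if p.op == "in":
        return value in tuple(p.value)
    if p.op == "=":
        return value == p.value
    if p.op == "!=":
        return value != p.value
    raise MatchEvalError(f"unknown operator {p.op!r}")


# --------------------------------------------------------------------------
# Component and treatment matching
# --------------------------------------------------------------------------

def _dose_satisfies(constraint, dose, ctx: MatchContext, inn: str) -> bool:
    if dose is None:
        return False
    want = constraint.quantity
    if (dose.unit, dose.per) != (want.unit, want.per):
        ctx.note(f"dose units differ for {inn or 'drug'} "
                 f"({dose.unit}/{dose.per} vs {want.unit}/{want.per}); "
                 "constraint not comparable")
        return False
    v, ref = dose.value, want.value
    return {"=": v == ref, "!=": v != ref, "<": v < ref,
            "<=": v <= ref, ">": v > ref, ">=": v >= ref}[constraint.op]


def match_component(cp: ComponentPattern,
                    comp: Union[DrugLine, NonDrug],
                    ctx: MatchContext) -> bool:
    """Match one non-wildcard pattern slot against one treatment component."""
    if cp.kind == "non_drug":
        return isinstance(comp, NonDrug) and comp.name == cp.non_drug
    if cp.kind == "drug_class_ref":
        if not isinstance(comp, DrugLine):
            return False
        cls: Optional[DrugClass] = ctx.kb.drug_classes.get(cp.drug_class)
        if cls is None or not cls.contains(comp.atc_code):
            return False
        if cp.dose is not None and not _dose_satisfies(cp.dose, comp.dose,
                                                       ctx, comp.inn):
            return False
        if cp.form is not None and comp.form != cp.form:
            return False
        if cp.tolerance is not None and comp.tolerance != cp.tolerance:
            return False  # unknown tolerance never satisfies a constraint
        return True
    raise ValueError(f"cannot match component kind {cp.kind!r}")


def _injective_assignment(concrete: Sequence[ComponentPattern],
                          components: Sequence[Union[DrugLine, NonDrug]],
                          ctx: MatchContext) -> Optional[int]:
    """Backtracking search for an injective slot->component assignment.

    Returns the number of leftover (unmatched) treatment components, or
    None when no assignment exists.  Treatments are small (a handful of
    components), so exhaustive backtracking is fine.
    """
    n = len(components)
    used = [False] * n

    def rec(i: int) -> bool:
        if i == len(concrete):
            return True
        for j in range(n):
            if used[j]:
                continue
            if match_component(concrete[i], components[j], ctx):
                used[j] = True
                if rec(i + 1):
                    return True
                used[j] = False
        return False

    if not rec(0):
        return None
    return n - len(concrete)


def match_treatment(t: Treatment, pat: TreatmentPattern,
                    ctx: MatchContext) -> bool:
    """True iff the treatment satisfies every constraint of the pattern."""
    if pat.status is not None and t.status != pat.status:
        return False
    if pat.efficacy is not None and t.visible_efficacy() != pat.efficacy:
        return False
    if pat.failed is not None and t.is_failed() != pat.failed:
        return False
    if pat.overall_tolerance is not None:
        drugs = t.drugs
        if pat.overall_tolerance == "well_tolerated":
            if not drugs or any(d.tolerance != "well_tolerated" for d in drugs):
                return False
        else:  # poorly_tolerated: at least one drug poorly tolerated
            if not any(d.tolerance == "poorly_tolerated" for d in drugs):
                return False
    if pat.changes and not (t.change_flags & pat.changes):
        return False
    if pat.cardinality is not None and len(t.drugs) != pat.cardinality:
        return False
    if pat.window_days is not None:
        if ctx.record.critique_date is None:
            ctx.note("missing data: critique date (time-window constraint)")
            return False
        anchor = t.end_date if t.status == "past" else ctx.record.critique_date
        if anchor is None:
            ctx.note("missing data: treatment end date (time-window constraint)")
            return False
        if (ctx.record.critique_date - anchor).days > pat.window_days:
            return False
    if not pat.components:
        return True
    concrete = [c for c in pat.components if c.kind != "any_wildcard"]
    wildcards = [c for c in pat.components if c.kind == "any_wildcard"]
    leftover = _injective_assignment(concrete, t.components, ctx)
    if leftover is None:
        return False
    lo = sum(w.min_repeat for w in wildcards)
    hi = (None if any(w.max_repeat is None for w in wildcards)
          else sum(w.max_repeat for w in wildcards))
    if not wildcards:
        return leftover == 0
    return leftover >= lo and (hi is None or leftover <= hi)


def history_exists(pat: TreatmentPattern, ctx: MatchContext,
                   scope: str = "any") -> bool:
    """Existential quantification over the therapeutic record.

    ``scope='history'`` looks at past and current treatments, ``'proposed'``
    only at the physician's proposal, ``'any'`` at both; the pattern's own
    status constraint filters further inside :func:`match_treatment`.
    A pattern without a status constraint matches treatments of any status.
    """
    candidates: list[Treatment] = []
    if scope in ("history", "any"):
        candidates.extend(ctx.record.history)
    if scope in ("proposed", "any") and ctx.record.proposed is not None:
        candidates.append(ctx.record.proposed)
    return any(match_treatment(t, pat, ctx) for t in candidates)


# --------------------------------------------------------------------------
# Native tests (used by compiled generic rules)
# --------------------------------------------------------------------------

def treatment_matches_template(t: Treatment, template: TreatmentTemplate) -> bool:
    """Treatment identity at INN granularity: same multiset of drug INNs
    and same non-drug components (doses and forms are not compared — a
    represcription "of treatment T" at another dose is still T)."""
    t_inns = sorted(d.inn for d in t.drugs)
    tpl_inns = sorted(d.inn for d in template.drugs)
    tpl_nd = {c.name for c in template.components if isinstance(c, NonDrug)}
    return t_inns == tpl_inns and t.non_drug_names == tpl_nd


def _native_current_conforms(ctx: MatchContext, params: dict) -> bool:
    """Current treatment is recommended by the guideline, effective, and
    every drug of it is well tolerated (generic recommendation #1)."""
    cur = ctx.record.current()
    if cur is None:
        return False
    if cur.visible_efficacy() != "effective":
        return False
    if not cur.drugs or any(d.tolerance != "well_tolerated" for d in cur.drugs):
        return False
    return any(treatment_matches_template(cur, tpl)
               for tpl in ctx.kb.recommendable_treatments)


def _native_represcribed_ineffective_treatment(ctx: MatchContext,
                                               params: dict) -> bool:
    """Generic #5: the proposal is recommendable treatment T, and the
    history holds an ineffective T within the window (default three years)
    that was stopped — i.e. not followed by another T."""
    template = ctx.kb.template(params["treatment"])
    window = int(params.get("window_days", 1095))
    proposed = ctx.record.proposed
    if proposed is None or not treatment_matches_template(proposed, template):
        return False
    if ctx.record.critique_date is None:
        ctx.note("missing data: critique date (recent-past constraint)")
        return False
    ordered = ctx.record.ordered_history()
    for i, t in enumerate(ordered):
        if t.status != "past" or not treatment_matches_template(t, template):
            continue
        if t.visible_efficacy() != "ineffective":
            continue
        if t.end_date is None or \
                (ctx.record.critique_date - t.end_date).days > window:
            continue
        followed_by_same = any(treatment_matches_template(u, template)
                               for u in ordered[i + 1:])
        if not followed_by_same:
            return True
    return False


def _native_represcribed_poorly_tolerated_class(ctx: MatchContext,
                                                params: dict) -> bool:
    """Generic #6: the proposal includes a drug of class C, and the history
    holds a past treatment with a poorly tolerated drug of C that was
    stopped — followed by a treatment without any drug of C."""
    cls = ctx.kb.drug_classes[params["drug_class"]]
    proposed = ctx.record.proposed
    if proposed is None or not any(cls.contains(d.atc_code)
                                   for d in proposed.drugs):
        return False
    ordered = ctx.record.ordered_history()
    for i, t in enumerate(ordered):
        if t.status != "past":
            continue
        if not any(cls.contains(d.atc_code) and d.tolerance == "poorly_tolerated"
                   for d in t.drugs):
            continue
        stopped = any(not any(cls.contains(d.atc_code) for d in u.drugs)
                      for u in ordered[i + 1:])
        if stopped:
            return True
    return False


_NATIVES: dict[str, Callable[[MatchContext, dict], bool]] = {
    "current_conforms_effective_well_tolerated": _native_current_conforms,
    "represcribed_ineffective_treatment": _native_represcribed_ineffective_treatment,
    "represcribed_poorly_tolerated_class": _native_represcribed_poorly_tolerated_class,
}


# --------------------------------------------------------------------------
# Condition expressions
# --------------------------------------------------------------------------

def eval_condition(expr: Cond, ctx: MatchContext) -> bool:
    """Recursive boolean evaluation.  Short-circuits on AND/OR, which is
    observationally identical to full evaluation (leaves are pure)."""
    if expr.kind == "true":
        return True
    if expr.kind == "and":
        return all(eval_condition(c, ctx) for c in expr.children)
    if expr.kind == "or":
        return any(eval_condition(c, ctx) for c in expr.children)
    if expr.kind == "not":
        return not eval_condition(expr.children[0], ctx)
    if expr.kind == "clinical":
        return eval_predicate(expr.predicate, ctx)
    if expr.kind == "therapeutic":
        return history_exists(expr.pattern, ctx, scope=expr.scope)
    if expr.kind == "native":
        fn = _NATIVES.get(expr.native)
        if fn is None:
            raise MatchEvalError(f"unknown native test {expr.native!r}")
        return fn(ctx, dict(expr.params))
    raise MatchEvalError(f"unknown condition kind {expr.kind!r}")
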