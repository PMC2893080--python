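"""Pattern and condition matching, checked against brute-force oracles."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxcritic.kb_model import (
    AND,
    ANY,
    CLIN,
    NOT,
    OR,
    THER,
    ComponentPattern,
    Cond,
    TreatmentPattern,
    kb_from_dict,
)
from rxcritic.matching import (
    MatchContext,
    MatchEvalError,
    eval_condition,
    eval_predicate,
    history_exists,
    match_component,
    match_treatment,
)
from rxcritic.patient_model import patient_from_dict

from conftest import simple_drug

KB = kb_from_dict({
    "name": "match_toy",
    "drug_classes": {
        "metformin": ["A10BA02"],
        "sulfonamide": ["A10BB"],
        "oral_antidiabetic": ["A10B"],
        "beta_blocker": ["C07A"],
    },
    "non_drugs": ["diet"],
    "attributes": {
        "age": {"type": "number", "grid": [14, 75]},
        "diabetic": {"type": "string", "grid": ["yes", "no"]},
        "HbA1c": {"type": "number", "grid": [6.0, 7.0]},
    },
    "recommendable_treatments": [
        {"name": "diet_metformin", "components": [
            {"non_drug": "diet"}, simple_drug("A10BA02", "metformin", 850)]}],
    "recommendations": [
        {"id": "r", "type": "should_prescribe",
         "lines": [[{"components": [{"non_drug": "diet"},
                                    {"class": "metformin"}]}]],
         "explanation_labels": {2: "x"}, "advice_labels": {1: "y"}}],
})


def ctx_for(doc) -> MatchContext:
    return MatchContext(record=patient_from_dict(doc), kb=KB)


def comp_class(name, **kw) -> ComponentPattern:
    return ComponentPattern(kind="drug_class_ref", drug_class=name, **kw)


class TestPredicates:
    @pytest.mark.parametrize("attr,op,value,patient,expected", [
        ("age", "<", 75, {"age": 80}, False),
        ("age", "<", 75, {"age": 60}, True),
        ("diabetic", "=", "yes", {"diabetic": "yes"}, True),
        ("diabetic", "!=", "yes", {"diabetic": "yes"}, False),
        ("age", "in", (14, 18), {"age": 18}, True),
    ])
    def test_comparison_semantics(self, attr, op, value, patient, expected):
        ctx = ctx_for({"clinical": patient})
        assert eval_predicate(
            CLIN(attr, op, value).predicate, ctx) is expected

    def test_missing_attribute_fails_closed_with_note(self):
        ctx = ctx_for({"clinical": {}})
        assert eval_predicate(CLIN("HbA1c", "<=", 6.5).predicate, ctx) is False
        assert any("missing data: HbA1c" in n for n in ctx.notes)

    def test_type_mismatch_names_attribute(self):
        ctx = ctx_for({"clinical": {"age": "old"}})
        with pytest.raises(MatchEvalError, match="age"):
            eval_predicate(CLIN("age", "<", 75).predicate, ctx)


class TestTreatmentMatching:
    def proposal(self, components):
        doc = {"critique_date": "2009-12-01",
               "proposed": {"components": components}}
        ctx = ctx_for(doc)
        return ctx.record.proposed, ctx

    def test_exact_component_match(self):
        t, ctx = self.proposal([{"non_drug": "diet"},
                                simple_drug("A10BA02", "metformin", 850)])
        pat = TreatmentPattern(components=(
            ComponentPattern(kind="non_drug", non_drug="diet"),
            comp_class("metformin")), status="proposed")
        assert match_treatment(t, pat, ctx)

    def test_cardinality_counts_drugs_only(self):
        """Diet + one oral drug is a monotherapy; a second drug breaks it."""
        mono, ctx = self.proposal([{"non_drug": "diet"},
                                   simple_drug("A10BA02", "metformin", 850)])
        pat = TreatmentPattern(components=(ANY,), cardinality=1)
        assert match_treatment(mono, pat, ctx)
        bi, ctx = self.proposal([{"non_drug": "diet"},
                                 simple_drug("A10BA02", "metformin", 850),
                                 simple_drug("A10BB01", "glibenclamide", 5)])
        assert not match_treatment(bi, pat, ctx)

    def test_wildcard_absorbs_extra_components(self):
        t, ctx = self.proposal([{"non_drug": "diet"},
                                simple_drug("A10BA02", "metformin", 850),
                                simple_drug("A10BB01", "glibenclamide", 5)])
        without_any = TreatmentPattern(components=(comp_class("metformin"),))
        with_any = TreatmentPattern(components=(comp_class("metformin"), ANY))
        assert not match_treatment(t, without_any, ctx)
        assert match_treatment(t, with_any, ctx)

    def test_injective_assignment_requires_distinct_components(self):
        """Two slots of the same class need two distinct drugs (the
        association rule's semantics)."""
        pat = TreatmentPattern(components=(comp_class("beta_blocker"),
                                           comp_class("beta_blocker"), ANY))
        one, ctx = self.proposal([simple_drug("C07AB02", "metoprolol", 100)])
        assert not match_treatment(one, pat, ctx)
        two, ctx = self.proposal([simple_drug("C07AB02", "metoprolol", 100),
                                  simple_drug("C07AB07", "bisoprolol", 5)])
        assert match_treatment(two, pat, ctx)

    def test_dose_and_tolerance_constraints_fail_closed(self):
        from rxcritic.kb_model import DoseConstraint, Quantity
        t, ctx = self.proposal([simple_drug("A10BA02", "metformin", 850)])
        dose_pat = TreatmentPattern(components=(
            comp_class("metformin",
                       dose=DoseConstraint(">=", Quantity(1000, "mg"))),))
        assert not match_treatment(t, dose_pat, ctx)
        tol_pat = TreatmentPattern(components=(
            comp_class("metformin", tolerance="well_tolerated"),))
        assert not match_treatment(t, tol_pat, ctx)  # tolerance unknown

    def test_time_window(self):
        """A three-year window measured from the treatment's end date."""
        pat = TreatmentPattern(components=(comp_class("metformin"), ANY),
                               window_days=3 * 365)
        def hist(end):
            return ctx_for({
                "critique_date": "2009-12-01",
                "history": [{"status": "past", "start": "2004-01-01",
                             "end": end,
                             "components": [simple_drug("A10BA02",
                                                        "metformin", 850)]}]})
        assert history_exists(pat, hist("2008-01-01"), scope="history")
        assert not history_exists(pat, hist("2005-11-01"), scope="history")


class TestHistoryExists:
    def test_past_failure_found(self):
        ctx = ctx_for({
            "critique_date": "2009-12-01",
            "history": [{"status": "past", "efficacy": "ineffective",
                         "start": "2009-01-01", "end": "2009-06-01",
                         "components": [{"non_drug": "diet"},
                                        simple_drug("A10BA02", "metformin",
                                                    850)]}]})
        pat = TreatmentPattern(components=(comp_class("metformin"), ANY),
                               status="past", efficacy="ineffective")
        assert history_exists(pat, ctx, scope="history")

    def test_empty_history_matches_nothing(self):
        ctx = ctx_for({"critique_date": "2009-12-01"})
        pat = TreatmentPattern(components=(ANY,), status="past")
        assert not history_exists(pat, ctx)

    def test_pattern_without_status_matches_any_status(self):
        ctx = ctx_for({
            "critique_date": "2009-12-01",
            "proposed": {"components": [simple_drug("A10BA02", "metformin",
                                                    850)]}})
        pat = TreatmentPattern(components=(comp_class("metformin"),))
        assert history_exists(pat, ctx, scope="any")
        assert not history_exists(pat, ctx, scope="history")


# --------------------------------------------------------------------------
# Brute-force oracles
# --------------------------------------------------------------------------

_POOL = [("A10BA02", "metformin"), ("A10BB01", "glibenclamide"),
         ("C07AB02", "metoprolol"), ("C07AB07", "bisoprolol")]
_CLASSES = ["metformin", "sulfonamide", "oral_antidiabetic", "beta_blocker"]


def _random_treatment(rng):
    n = rng.randint(1, 5)
    comps = []
    for _ in range(n):
        if rng.random() < 0.25:
            comps.append({"non_drug": "diet"})
        else:
            atc, inn = rng.choice(_POOL)
            comps.append(simple_drug(atc, inn, rng.choice([100, 500])))
    doc = {"critique_date": "2009-12-01", "proposed": {"components": comps}}
    ctx = ctx_for(doc)
    return ctx.record.proposed, ctx


def _random_pattern(rng, with_wildcard=None):
    comps = []
    for _ in range(rng.randint(0, 3)):
        if rng.random() < 0.2:
            comps.append(ComponentPattern(kind="non_drug", non_drug="diet"))
        else:
            comps.append(comp_class(rng.choice(_CLASSES)))
    if with_wildcard is None:
        with_wildcard = rng.random() < 0.5
    if with_wildcard:
        comps.append(ANY)
    if not comps:
        comps = [ANY]
    return TreatmentPattern(components=tuple(comps))


def _brute_force_match(t, pat, ctx):
    """Enumerate every injective slot assignment via permutations."""
    concrete = [c for c in pat.components if c.kind != "any_wildcard"]
    has_wildcard = any(c.kind == "any_wildcard" for c in pat.components)
    comps = t.components
    if len(concrete) > len(comps):
        return False
    for perm in itertools.permutations(range(len(comps)), len(concrete)):
        if all(match_component(cp, comps[j], ctx)
               for cp, j in zip(concrete, perm)):
            leftover = len(comps) - len(concrete)
            if has_wildcard or leftover == 0:
                return True
    return False


class TestMatchingProperties:
    def test_match_equals_brute_force_enumeration(self):
        rng = random.Random(7)
        checked = 0
        for _ in range(300):
            t, ctx = _random_treatment(rng)
            pat = _random_pattern(rng)
            assert match_treatment(t, pat, ctx) == \
                _brute_force_match(t, pat, ctx)
            checked += 1
        assert checked == 300

    def test_adding_wildcard_is_monotone(self):
        """An unconstrained wildcard never turns a match into a miss."""
        rng = random.Random(11)
        for _ in range(200):
            t, ctx = _random_treatment(rng)
            pat = _random_pattern(rng, with_wildcard=False)
            if match_treatment(t, pat, ctx):
                widened = TreatmentPattern(components=pat.components + (ANY,))
                assert match_treatment(t, widened, ctx)


# --------------------------------------------------------------------------
# Condition expressions
# --------------------------------------------------------------------------

def _leaf(i: int) -> Cond:
    return CLIN(f"f{i}", "=", 1)


_LEAF_KB = kb_from_dict({
    "name": "bool_toy",
    "drug_classes": {"c": ["A10BA02"]},
    "attributes": {f"f{i}": {"type": "number", "grid": [0, 1]}
                   for i in range(4)},
    "recommendable_treatments": [
        {"name": "t", "components": [simple_drug("A10BA02", "m", 1)]}],
    "recommendations": [
        {"id": "r", "type": "should_prescribe",
         "lines": [[{"components": [{"class": "c"}]}]],
         "explanation_labels": {2: "x"}, "advice_labels": {1: "y"}}],
})


def _interp(expr: Cond, assignment: dict) -> bool:
    """Independent interpreter over boolean-leaf expressions."""
    if expr.kind == "and":
        return all(_interp(c, assignment) for c in expr.children)
    if expr.kind == "or":
        return any(_interp(c, assignment) for c in expr.children)
    if expr.kind == "not":
        return not _interp(expr.children[0], assignment)
    return assignment[expr.predicate.attribute] == 1


def _eval_on(expr: Cond, assignment: dict) -> bool:
    record = patient_from_dict({"clinical": dict(assignment)})
    return eval_condition(expr, MatchContext(record=record, kb=_LEAF_KB))


@st.composite
def bool_exprs(draw, depth=0):
    if depth >= 3 or draw(st.booleans()):
        return _leaf(draw(st.integers(0, 3)))
    kind = draw(st.sampled_from(["and", "or", "not"]))
    if kind == "not":
        return NOT(draw(bool_exprs(depth=depth + 1)))
    children = draw(st.lists(bool_exprs(depth=depth + 1), min_size=2,
                             max_size=3))
    return Cond(kind=kind, children=tuple(children))


class TestConditionExpressions:
    def test_not_false_is_true(self):
        ctx = MatchContext(record=patient_from_dict({}), kb=_LEAF_KB)
        assert eval_condition(NOT(CLIN("f0", "=", 1)), ctx)

    def test_monotherapy_and_hba1c_conjunction(self):
        """The worked example's applicability condition on its stage-1
        patient."""
        kb = KB
        record = patient_from_dict({
            "biological": {"HbA1c": 6.2}, "critique_date": "2009-12-01",
            "proposed": {"components": [
                {"non_drug": "diet"},
                simple_drug("A10BA02", "metformin", 850)]}})
        cond = AND(THER(TreatmentPattern(components=(ANY,), cardinality=1),
                        scope="proposed"),
                   CLIN("HbA1c", "<=", 6.5))
        assert eval_condition(cond, MatchContext(record=record, kb=kb))

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(bool_exprs())
    def test_matches_truth_table_brute_force(self, expr):
        for values in itertools.product((0, 1), repeat=4):
            assignment = {f"f{i}": v for i, v in enumerate(values)}
            assert _eval_on(expr, assignment) == _interp(expr, assignment)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(bool_exprs(), bool_exprs())
    def test_de_morgan_duality(self, a, b):
        for values in itertools.product((0, 1), repeat=4):
            assignment = {f"f{i}": v for i, v in enumerate(values)}
            assert _eval_on(NOT(AND(a, b)), assignment) == \
                _eval_on(OR(NOT(a), NOT(b)), assignment)
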