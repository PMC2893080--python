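"""Rule generation: counts, stage conditions, label composition, generics."""

import random

import pytest

from conftest import TEXT_STAGE1_AGI, simple_drug
from rxcritic.fixtures import generic_exercise_kb, random_small_kb
from rxcritic.kb_model import kb_from_dict
from rxcritic.matching import MatchContext, eval_condition
from rxcritic.patient_model import patient_from_dict
from rxcritic.rule_compiler import (
    CompileError,
    compile_generic,
    compile_increasing_power,
    compile_kb,
    compile_should_not_prescribe,
    compile_should_prescribe,
    stage_condition,
)

_ROOTS = ["A02B", "A10B", "C03C", "C07A", "C09A", "N06A"]


def n_line_kb(n, rec_type="should_prescribe", generics=False, conditions=None):
    """A KB whose single recommendation has n lines/levels, one class each."""
    doc = {
        "name": f"nl{n}",
        "drug_classes": {f"cls{i}": [_ROOTS[i]] for i in range(n)},
        "recommendable_treatments": [
            {"name": f"t{i}", "components": [
                simple_drug(f"{_ROOTS[i]}A01", f"drug{i}", 10 * (i + 1))]}
            for i in range(n)],
        "recommendations": [{
            "id": "rec", "type": rec_type,
            "lines": [[{"components": [{"class": f"cls{i}"}]}]
                      for i in range(n)],
        }],
        "generic": {} if generics else {
            "applicability": {i: "not_applicable" for i in range(1, 9)}},
    }
    rec = doc["recommendations"][0]
    if conditions:
        rec["conditions"] = conditions
    if rec_type == "should_prescribe":
        rec["explanation_labels"] = {y: f"Line-{y} proposal."
                                     for y in range(2, n + 2)}
        rec["advice_labels"] = {x: f"Stage-{x} advice."
                                for x in range(1, n + 1)}
    else:
        rec["criticism_label"] = "Weaker than a failed treatment."
    return kb_from_dict(doc)


def history_doc(failed_lines, n, critique="2009-12-01"):
    """History with one ineffective treatment per given line index (1-based)."""
    hist = []
    for j, line in enumerate(failed_lines):
        hist.append({
            "status": "past", "efficacy": "ineffective",
            "start": f"2008-0{j + 1}-01", "end": f"2008-0{j + 2}-01",
            "components": [simple_drug(f"{_ROOTS[line - 1]}A01",
                                       f"drug{line - 1}", 10 * line)]})
    return {"critique_date": critique, "history": hist,
            "proposed": {"components": [simple_drug(f"{_ROOTS[0]}A01",
                                                    "drug0", 10)]}}


class TestRuleCounts:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_should_prescribe_yields_n_times_n_plus_1_over_2(self, n):
        kb = n_line_kb(n)
        rules = compile_should_prescribe(kb.recommendations[0])
        assert len(rules) == n * (n + 1) // 2
        pairs = {(r.X, r.Y) for r in rules}
        assert pairs == {(x, y) for x in range(1, n + 1)
                         for y in range(x + 1, n + 2)}

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 2), (5, 4)])
    def test_increasing_power_yields_n_minus_1(self, n, expected):
        kb = n_line_kb(n, rec_type="increasing_power")
        assert len(compile_increasing_power(kb.recommendations[0])) == expected

    def test_increasing_power_needs_two_levels(self):
        from rxcritic.kb_model import KBValidationError
        with pytest.raises(KBValidationError):
            n_line_kb(1, rec_type="increasing_power")  # rejected at load
        kb = n_line_kb(3, rec_type="increasing_power")
        from dataclasses import replace
        broken = replace(kb.recommendations[0], lines=kb.recommendations[0]
                         .lines[:1])
        with pytest.raises(CompileError, match="N >= 2"):
            compile_increasing_power(broken)

    def test_should_not_prescribe_yields_one_rule(self):
        kb = kb_from_dict({
            "name": "snp",
            "drug_classes": {"glitazone": ["A10BG"]},
            "recommendable_treatments": [
                {"name": "t", "components": [simple_drug("A10BG02",
                                                         "rosiglitazone",
                                                         4)]}],
            "recommendations": [{
                "id": "no_glitazone", "type": "should_not_prescribe",
                "forbidden": {"components": [{"class": "glitazone"}, "any"]},
                "criticism_label": "Glitazones are not recommended here."}],
        })
        rules = compile_should_not_prescribe(kb.recommendations[0])
        assert len(rules) == 1
        assert not rules[0].relaxable

    def test_closed_forms_on_randomized_n(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(1, 5)
            rules = compile_should_prescribe(
                n_line_kb(n).recommendations[0])
            assert len(rules) == n * (n + 1) // 2
            if n >= 2:
                rules = compile_increasing_power(
                    n_line_kb(n, rec_type="increasing_power")
                    .recommendations[0])
                assert len(rules) == n - 1

    def test_compile_kb_concatenates_deterministically(self, dkb):
        rs1, rs2 = compile_kb(dkb), compile_kb(dkb)
        assert rs1.to_json() == rs2.to_json()
        assert len(rs1) == 3  # worked example with generics disabled


class TestWorkedExampleRules:
    def test_three_rules_with_expected_ids(self, dkb_rules):
        assert [r.id for r in dkb_rules.rules] == [
            "monotherapy_choice:X1Y2", "monotherapy_choice:X1Y3",
            "monotherapy_choice:X2Y3"]

    def test_x1_y2_criticism_is_the_matrix_cell_text(self, dkb_rules):
        rule = next(r for r in dkb_rules.rules if (r.X, r.Y) == (1, 2))
        assert rule.criticism == TEXT_STAGE1_AGI

    def test_label_sharing_across_rows_and_columns(self):
        """Rules sharing a patient stage share their advice fragment; rules
        sharing a proposal line share their explanation fragment."""
        kb = n_line_kb(3)
        rules = compile_should_prescribe(kb.recommendations[0])
        for r in rules:
            assert f"Stage-{r.X} advice." in r.criticism
            assert r.criticism.startswith(f"Line-{r.Y} proposal.")

    def test_missing_reachable_label_is_a_compile_error(self):
        kb = n_line_kb(2)
        from dataclasses import replace
        broken = replace(kb.recommendations[0], advice_labels={1: "only one"})
        with pytest.raises(CompileError, match="advice label for line 2"):
            compile_should_prescribe(broken)


class TestStageConditions:
    def eval_stage(self, kb, x, doc):
        from rxcritic.engine import prepare_record
        record = prepare_record(patient_from_dict(doc), kb)
        ctx = MatchContext(record=record, kb=kb)
        return eval_condition(stage_condition(kb.recommendations[0], x), ctx)

    def test_empty_history_is_stage_one_only(self):
        kb = n_line_kb(2)
        doc = history_doc([], 2)
        assert self.eval_stage(kb, 1, doc)
        assert not self.eval_stage(kb, 2, doc)

    def test_failed_first_line_is_stage_two(self):
        kb = n_line_kb(2)
        doc = history_doc([1], 2)
        assert not self.eval_stage(kb, 1, doc)
        assert self.eval_stage(kb, 2, doc)

    def test_three_lines_failed_first_only_is_stage_two_uniquely(self):
        kb = n_line_kb(3)
        doc = history_doc([1], 3)
        assert [self.eval_stage(kb, x, doc) for x in (1, 2, 3)] == \
            [False, True, False]

    def test_poor_tolerance_also_advances_stage(self):
        kb = n_line_kb(2)
        doc = history_doc([], 2)
        doc["history"] = [{
            "status": "past", "start": "2008-01-01", "end": "2008-06-01",
            "components": [simple_drug(f"{_ROOTS[0]}A01", "drug0", 10,
                                       tolerance="poorly_tolerated")]}]
        assert self.eval_stage(kb, 2, doc)

    def test_stage_out_of_range_rejected(self):
        kb = n_line_kb(2)
        with pytest.raises(ValueError, match="out of range"):
            stage_condition(kb.recommendations[0], 3)

    def test_stage_partition_over_random_histories(self):
        """For N >= 2, histories whose failures fall on the
        recommendation's own lines satisfy exactly one stage condition."""
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(2, 4)
            kb = n_line_kb(n)
            failed = [line for line in range(1, n + 1) if rng.random() < 0.4]
            doc = history_doc(failed, n)
            truths = [self.eval_stage(kb, x, doc) for x in range(1, n + 1)]
            assert sum(truths) == 1, (failed, truths)

    def test_single_line_recommendation_edge(self):
        """With N = 1 the stage-1 clause ("no failed treatment of any
        line") is also the only clause: a patient whose sole line already
        failed has no stage, so the recommendation goes silent and the
        failed-treatment policing is left to the generic recommendations."""
        kb = n_line_kb(1)
        assert not self.eval_stage(kb, 1, history_doc([1], 1))
        assert self.eval_stage(kb, 1, history_doc([], 1))


class TestIncreasingPowerSemantics:
    def test_weaker_after_stronger_failure_fires(self):
        """Fibrates after an ineffective statin: the single rule of a
        two-level power ordering fires."""
        kb = kb_from_dict({
            "name": "power",
            "drug_classes": {"fibrate": ["C10AB"], "statin": ["C10AA"]},
            "recommendable_treatments": [
                {"name": "simvastatin", "components": [
                    simple_drug("C10AA01", "simvastatin", 20)]}],
            "recommendations": [{
                "id": "statins_over_fibrates", "type": "increasing_power",
                "lines": [[{"components": [{"class": "fibrate"}]}],
                          [{"components": [{"class": "statin"}]}]],
                "criticism_label": "Statins are more effective than "
                                   "fibrates.",
            }],
            "generic": {"applicability": {i: "not_applicable"
                                          for i in range(1, 9)}},
        })
        rules = compile_increasing_power(kb.recommendations[0])
        assert len(rules) == 1
        doc = {
            "critique_date": "2009-12-01",
            "history": [{"status": "past", "efficacy": "ineffective",
                         "start": "2009-01-01", "end": "2009-06-01",
                         "components": [simple_drug("C10AA01", "simvastatin",
                                                    20)]}],
            "proposed": {"components": [simple_drug("C10AB05", "fenofibrate",
                                                    145)]},
        }
        from rxcritic.engine import prepare_record
        record = prepare_record(patient_from_dict(doc), kb)
        ctx = MatchContext(record=record, kb=kb)
        assert eval_condition(rules[0].condition, ctx)
        # proposing the statin itself triggers nothing
        doc["proposed"] = {"components": [simple_drug("C10AA05",
                                                      "atorvastatin", 10)]}
        record = prepare_record(patient_from_dict(doc), kb)
        assert not eval_condition(rules[0].condition,
                                  MatchContext(record=record, kb=kb))


class TestGenericCompilation:
    def test_dose_related_block_yields_three_rules(self, gkb):
        rules = compile_generic(gkb)
        dose_ids = [r.id for r in rules if r.id in ("generic#2", "generic#3",
                                                    "generic#4")]
        assert dose_ids == ["generic#2", "generic#3", "generic#4"]

    def test_per_entity_counts(self):
        """4 recommendable treatments and 3 classes, all applicable:
        1 + 3 + 4 + 3 + 3 = 14 generic rules."""
        doc = {
            "name": "counts",
            "drug_classes": {f"cls{i}": [_ROOTS[i]] for i in range(3)},
            "recommendable_treatments": [
                {"name": f"t{i}", "components": [
                    simple_drug(f"{_ROOTS[min(i, 2)]}A0{i}", f"d{i}",
                                10 + i)]}
                for i in range(4)],
            "recommendations": [{
                "id": "r", "type": "should_prescribe",
                "lines": [[{"components": [{"class": "cls0"}]}]],
                "explanation_labels": {2: "x"}, "advice_labels": {1: "y"}}],
        }
        kb = kb_from_dict(doc)
        assert len(compile_generic(kb)) == 14

    def test_not_applicable_items_are_omitted(self, dkb):
        assert compile_generic(dkb) == []

    def test_generic_seven_produces_no_rule(self, gkb):
        assert not any(r.source == "generic#7" for r in compile_generic(gkb))

    def test_bupropion_exception_excludes_it_from_dose_decrease_rule(self, gkb):
        rule4 = next(r for r in compile_generic(gkb) if r.id == "generic#4")
        # the exception adds a NOT(proposal contains bupropion) conjunct
        doc = {
            "critique_date": "2009-12-01",
            "history": [{"status": "current", "start": "2009-01-01",
                         "components": [simple_drug(
                             "N06AX12", "bupropion", 300,
                             tolerance="poorly_tolerated")]}],
            "proposed": {"components": [simple_drug("N06AX12", "bupropion",
                                                    300)]},
        }
        from rxcritic.engine import prepare_record
        # dose increase on poorly tolerated bupropion: exempt, no criticism
        doc["proposed"]["components"][0]["drug"]["dose"]["value"] = 450
        record = prepare_record(patient_from_dict(doc), gkb)
        assert not eval_condition(rule4.condition,
                                  MatchContext(record=record, kb=gkb))
        # same situation with nicotine: the rule fires
        for part in (doc["history"][0], doc["proposed"]):
            part["components"][0] = simple_drug(
                "N07BA01", "nicotine", 15,
                tolerance="poorly_tolerated"
                if part is doc["history"][0] else None)
        doc["proposed"]["components"][0]["drug"]["dose"]["value"] = 30
        record = prepare_record(patient_from_dict(doc), gkb)
        assert eval_condition(rule4.condition,
                              MatchContext(record=record, kb=gkb))

    def test_exception_listed_entity_skipped_in_per_entity_rules(self, skb):
        ids = {r.id for r in compile_generic(skb)}
        assert "generic#6:simvastatin" in ids
        assert "generic#6:statin" not in ids  # umbrella class excepted
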