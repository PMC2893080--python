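"""Quality assurance: quasi-exhaustive verification and test-base generation.

The verification procedure treats the critiquing engine as a black box and
tries to regenerate the guideline knowledge from it:

1. enumerate (almost) all possible input vectors — the cartesian product
   of the finite value grids declared for each clinical attribute, crossed
   with encoded therapeutic-history features;
2. run the engine on every vector and record its output — the set of
   treatments accepted for that patient profile, with treatments accepted
   only under relaxation marked as "second-line only";
3. induce an *unpruned* decision tree (C4.5-style gain-ratio splitting)
   from the (vector, output) pairs — pruning stays disabled so the tree
   keeps 0% training error and is a faithful rewrite of the engine's
   behaviour, ready for a human reviewer to compare against the original
   guideline text.

The test-base generator implements the complementary hand-testing scheme:
for each patient profile, one positive case per treatment recommended for
that profile plus five seeded-random negative cases built from drug
classes outside the recommended set.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from itertools import product
from typing import Any, Callable, Optional, Sequence

from .engine import RuleSet, compile_kb, prepare_record, suggestion_min_k
from .kb_model import KnowledgeBase, NonDrug, Quantity, TreatmentTemplate
from .patient_model import (
    DrugLine,
    PatientRecord,
    Treatment,
    treatment_from_template,
)

__all__ = [
    "HistoryFeature",
    "default_history_features",
    "enumerate_vectors",
    "record_from_vector",
    "build_dataset",
    "label_for",
    "DecisionTree",
    "TreeNode",
    "induce_tree",
    "classify",
    "render_tree_text",
    "render_tree_dot",
    "TestCase",
    "TestBase",
    "generate_test_base",
    "run_test_base",
    "VerificationError",
    "NO_TREATMENT_LABEL",
    "CRITIQUE_DATE",
]

NO_TREATMENT_LABEL = "no treatment"

#: Fixed reference date for enumerated profiles (history features place
#: past treatments relative to it).
CRITIQUE_DATE = date(2010, 1, 1)


class VerificationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Input vectors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HistoryFeature:
    """One categorical therapeutic-history feature of the input vector.

    ``build(value)`` returns the past treatments the feature value stands
    for.  The default encoder exposes one feature per recommendable
    treatment with values none / ineffective / poorly_tolerated.
    """

    name: str
    values: tuple
    build: Callable[[Any], list[Treatment]]


def _past_treatment(template: TreatmentTemplate, outcome: str,
                    index: int) -> list[Treatment]:
    t = treatment_from_template(template, status="past")
    t.start_date = CRITIQUE_DATE - timedelta(days=700 + index)
    t.end_date = CRITIQUE_DATE - timedelta(days=300 + index)
    if outcome == "ineffective":
        t.efficacy = "ineffective"
        for d in t.drugs:
            d.tolerance = "well_tolerated"
        return [t]
    # poorly tolerated, stopped: mark the drugs and add the stopping
    # evidence (a later drug-free interval) so the "was stopped in the
    # past" clause of generic #6 is observable
    for d in t.drugs:
        d.tolerance = "poorly_tolerated"
    stop = Treatment(components=[NonDrug("none")], status="past",
                     start_date=t.end_date + timedelta(days=1),
                     end_date=t.end_date + timedelta(days=100))
    return [t, stop]


def default_history_features(kb: KnowledgeBase) -> list[HistoryFeature]:
    feats = []
    for i, template in enumerate(kb.recommendable_treatments):
        feats.append(HistoryFeature(
            name=f"past_{template.name}",
            values=("none", "ineffective", "poorly_tolerated"),
            build=(lambda v, tpl=template, idx=i:
                   [] if v == "none" else _past_treatment(tpl, v, idx))))
    return feats


def enumerate_vectors(kb: KnowledgeBase,
                      history_features: Optional[Sequence[HistoryFeature]] = None,
                      max_vectors: int = 100_000) -> list[dict]:
    """Full cartesian product of the declared attribute grids and history
    features, in deterministic declaration order.

    Every clinical attribute must declare a finite grid; an unbounded one
    aborts the enumeration with an error naming it (this mirrors skipping
    guidelines whose vector space is too large to review).
    """
    if history_features is None:
        history_features = default_history_features(kb)
    axes: list[tuple[str, tuple]] = []
    for name, decl in kb.attributes.items():
        if decl.grid is None:
            raise VerificationError(
                f"attribute {name!r} declares no finite value grid")
        axes.append((name, tuple(decl.grid)))
    axes.extend((f.name, tuple(f.values)) for f in history_features)
    count = math.prod(len(vals) for _, vals in axes) if axes else 0
    if count > max_vectors:
        raise VerificationError(
            f"{count} input vectors exceed the cap of {max_vectors}; "
            "the tree would not be human-readable")
    names = [n for n, _ in axes]
    return [dict(zip(names, combo))
            for combo in product(*(vals for _, vals in axes))]


def record_from_vector(vector: dict, kb: KnowledgeBase,
                       history_features: Optional[Sequence[HistoryFeature]] = None
                       ) -> PatientRecord:
    if history_features is None:
        history_features = default_history_features(kb)
    feature_names = {f.name for f in history_features}
    clinical = {k: v for k, v in vector.items() if k not in feature_names}
    history: list[Treatment] = []
    for f in history_features:
        if f.name in vector:
            history.extend(f.build(vector[f.name]))
    return PatientRecord(clinical=clinical, history=history,
                         critique_date=CRITIQUE_DATE)


def label_for(record: PatientRecord, kb: KnowledgeBase,
              ruleset: Optional[RuleSet] = None) -> str:
    """Canonical output label: accepted treatments in KB declaration
    order, bracketed when accepted only under relaxation (second-line
    only); "no treatment" when nothing is ever accepted."""
    min_k = suggestion_min_k(record, kb, ruleset)
    parts = []
    for template in kb.recommendable_treatments:
        k = min_k[template.name]
        if k is None:
            continue
        parts.append(template.name if k == 0 else f"[{template.name}]")
    return " + ".join(parts) if parts else NO_TREATMENT_LABEL


def build_dataset(kb: KnowledgeBase,
                  vectors: Optional[Sequence[dict]] = None,
                  history_features: Optional[Sequence[HistoryFeature]] = None,
                  ruleset: Optional[RuleSet] = None
                  ) -> list[tuple[dict, str]]:
    """(input vector, engine output) pairs over the whole enumeration."""
    if history_features is None:
        history_features = default_history_features(kb)
    if vectors is None:
        vectors = enumerate_vectors(kb, history_features)
    if ruleset is None:
        ruleset = compile_kb(kb)
    dataset = []
    for v in vectors:
        record = record_from_vector(v, kb, history_features)
        dataset.append((v, label_for(record, kb, ruleset)))
    return dataset


# --------------------------------------------------------------------------
# Decision-tree induction (C4.5-style, pruning disabled)
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    attribute: Optional[str] = None          # None at leaves
    branches: dict[Any, "TreeNode"] = field(default_factory=dict)
    label: Optional[str] = None              # set at leaves

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None


@dataclass
class DecisionTree:
    root: TreeNode
    feature_order: tuple[str, ...]
    training_error: float = 0.0

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return sum(count(c) for c in node.branches.values())
        return count(self.root)

    def paths(self) -> list[tuple[tuple[tuple[str, Any], ...], str]]:
        """All (condition path, leaf label) pairs, depth-first."""
        out: list[tuple[tuple[tuple[str, Any], ...], str]] = []

        def walk(node: TreeNode, path: tuple) -> None:
            if node.is_leaf:
                out.append((path, node.label))
                return
            for value, child in node.branches.items():
                walk(child, path + ((node.attribute, value),))

        walk(self.root, ())
        return out


def _entropy(labels: Sequence[str]) -> float:
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def _gain_ratio(rows: Sequence[tuple[dict, str]], attr: str
                ) -> tuple[float, float]:
    labels = [lbl for _, lbl in rows]
    base = _entropy(labels)
    groups: dict[Any, list[str]] = {}
    for v, lbl in rows:
        groups.setdefault(v[attr], []).append(lbl)
    if len(groups) < 2:
        return 0.0, 0.0
    n = len(rows)
    cond = sum(len(g) / n * _entropy(g) for g in groups.values())
    gain = base - cond
    split_info = _entropy([val for v, _ in rows for val in (v[attr],)])
    if split_info <= 0:
        return 0.0, 0.0
    return gain, gain / split_info


def induce_tree(dataset: Sequence[tuple[dict, str]],
                feature_order: Optional[Sequence[str]] = None) -> DecisionTree:
    """Greedy gain-ratio induction on categorical features, recursing until
    every leaf is label-pure; with pruning disabled the training error is
    0% by construction.  Ties break on feature declaration order."""
    if not dataset:
        raise VerificationError("empty dataset")
    if feature_order is None:
        feature_order = list(dataset[0][0].keys())
    feature_order = tuple(feature_order)

    def build(rows: Sequence[tuple[dict, str]]) -> TreeNode:
        labels = {lbl for _, lbl in rows}
        if len(labels) == 1:
            return TreeNode(label=next(iter(labels)))
        best_attr, best_ratio, best_gain = None, -1.0, 0.0
        for attr in feature_order:
            gain, ratio = _gain_ratio(rows, attr)
            if gain > 1e-12 and ratio > best_ratio + 1e-12:
                best_attr, best_ratio, best_gain = attr, ratio, gain
        if best_attr is None:
            # fall back to any attribute that still separates the rows;
            # the engine is deterministic, so identical vectors cannot
            # carry different labels — guard anyway
            for attr in feature_order:
                if len({v[attr] for v, _ in rows}) > 1:
                    best_attr = attr
                    break
        if best_attr is None:
            raise VerificationError(
                "contradictory duplicate records in the dataset")
        node = TreeNode(attribute=best_attr)
        groups: dict[Any, list[tuple[dict, str]]] = {}
        for v, lbl in rows:
            groups.setdefault(v[best_attr], []).append((v, lbl))
        for value in sorted(groups, key=repr):
            node.branches[value] = build(groups[value])
        return node

    tree = DecisionTree(root=build(list(dataset)), feature_order=feature_order)
    errors = sum(1 for v, lbl in dataset if classify(tree, v) != lbl)
    tree.training_error = errors / len(dataset)
    return tree


def classify(tree: DecisionTree, vector: dict) -> str:
    node = tree.root
    while not node.is_leaf:
        node = node.branches[vector[node.attribute]]
    return node.label


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def render_tree_text(tree: DecisionTree) -> str:
    """Indented text rendering; bracketed treatments at the leaves are
    recommended as second-line treatments only."""
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        indent = "|   " * depth
        if node.is_leaf:
            lines.append(f"{indent}-> {node.label}")
            return
        for value, child in node.branches.items():
            if child.is_leaf:
                lines.append(f"{indent}{node.attribute} = {value}: {child.label}")
            else:
                lines.append(f"{indent}{node.attribute} = {value}")
                walk(child, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines)


def render_tree_dot(tree: DecisionTree) -> str:
    """Graph-description (DOT) rendering with the same path set."""
    out = ["digraph decision_tree {", "  node [shape=box];"]
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            out.append(f'  n{nid} [label="{node.label}", shape=ellipse];')
            return nid
        out.append(f'  n{nid} [label="{node.attribute}"];')
        for value, child in node.branches.items():
            cid = walk(child)
            out.append(f'  n{nid} -> n{cid} [label="{value}"];')
        return nid

    walk(tree.root)
    out.append("}")
    return "\n".join(out)


# --------------------------------------------------------------------------
# Test-base generation
# --------------------------------------------------------------------------

@dataclass
class TestCase:
    patient: dict                 # serialized patient record
    expected_conforms: bool
    expected_relaxation: int = 0  # verdict checked at this relaxation level
    note: str = ""


@dataclass
class TestBase:
    kb_name: str
    seed: int
    cases: list[TestCase] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kb": self.kb_name, "seed": self.seed,
            "warnings": list(self.warnings),
            "cases": [{"patient": c.patient,
                       "expected_conforms": c.expected_conforms,
                       "expected_relaxation": c.expected_relaxation,
                       "note": c.note} for c in self.cases],
        }


def _negative_treatment(kb: KnowledgeBase, cls_name: str, dose_value: float,
                        template: TreatmentTemplate) -> Treatment:
    """A non-recommended treatment shaped like a recommendable one: keep
    the non-drug components, replace the drugs with a drug of the sampled
    class at the sampled dose."""
    cls = kb.drug_classes[cls_name]
    base = treatment_from_template(template)
    drugs = base.drugs
    unit = drugs[0].dose.unit if drugs and drugs[0].dose else "mg"
    atc = cls.atc_codes[0]
    # complete a class-level code into a structurally valid drug-level code
    atc += {1: "01AA01", 3: "AA01", 4: "A01", 5: "01"}.get(len(atc), "")
    new = Treatment(status="proposed")
    new.components = [c for c in base.components if isinstance(c, NonDrug)]
    new.components.append(DrugLine(
        atc_code=atc, inn=f"random_{cls_name}",
        dose=Quantity(value=dose_value, unit=unit)))
    return new


def _criticized(record: PatientRecord, kb: KnowledgeBase,
                ruleset: RuleSet) -> bool:
    from .matching import MatchContext, eval_condition
    prepared = prepare_record(record, kb)
    ctx = MatchContext(record=prepared, kb=kb)
    return any(eval_condition(r.condition, ctx)
               for r in ruleset.active_rules(0))


def _dose_grid(kb: KnowledgeBase) -> list[float]:
    doses = sorted({d.dose.value for t in kb.recommendable_treatments
                    for d in t.drugs if d.dose is not None})
    return doses or [100.0]


def generate_test_base(kb: KnowledgeBase,
                       profiles: Optional[Sequence[dict]] = None,
                       seed: int = 0, n_profiles: int = 4,
                       ruleset: Optional[RuleSet] = None) -> TestBase:
    """Per profile: one positive case per treatment recommended for that
    profile, plus five negative cases with seeded-random non-recommended
    treatments (drug class outside the recommended set, dose drawn from
    the KB's dose grid).  Identical seed, identical test base.
    """
    from .patient_model import patient_to_dict  # local: avoids cycle at import

    rng = random.Random(seed)
    if ruleset is None:
        ruleset = compile_kb(kb)
    features = default_history_features(kb)
    if profiles is None:
        vectors = enumerate_vectors(kb, features)
        idx = sorted(rng.sample(range(len(vectors)),
                                min(n_profiles, len(vectors))))
        profiles = [vectors[i] for i in idx]
    base = TestBase(kb_name=kb.name, seed=seed)

    for profile in profiles:
        record = record_from_vector(profile, kb, features)
        prepared = prepare_record(record, kb)
        min_k = suggestion_min_k(prepared, kb, ruleset, prepared=True)
        recommended = [t for t in kb.recommendable_treatments
                       if min_k[t.name] is not None]
        rec_classes = {c for t in recommended for d in t.drugs
                       for c in kb.drug_class_of(d.atc_code)}
        for template in recommended:
            pos = PatientRecord(clinical=dict(record.clinical),
                                biological=dict(record.biological),
                                history=list(record.history),
                                proposed=treatment_from_template(template),
                                critique_date=record.critique_date)
            base.cases.append(TestCase(
                patient=patient_to_dict(pos), expected_conforms=True,
                expected_relaxation=min_k[template.name],
                note=f"recommended: {template.name}"))
        candidates = sorted(set(kb.drug_classes) - rec_classes)
        shape = kb.recommendable_treatments[0]

        def neg_record(cls_name: str, dose_value: float) -> PatientRecord:
            return PatientRecord(clinical=dict(record.clinical),
                                 biological=dict(record.biological),
                                 history=list(record.history),
                                 proposed=_negative_treatment(
                                     kb, cls_name, dose_value, shape),
                                 critique_date=record.critique_date)

        # keep only pairs the engine actually criticizes: a negative case
        # asserts that a non-recommended treatment raises an alert, which
        # presupposes the guideline constrains this profile at all
        pairs = [(c, dv) for c in candidates for dv in _dose_grid(kb)
                 if _criticized(neg_record(c, dv), kb, ruleset)]
        if len(pairs) < 5:
            base.warnings.append(
                f"profile {profile}: only {len(pairs)} distinct criticized "
                "negative treatments constructible")
        chosen = rng.sample(pairs, min(5, len(pairs)))
        for cls_name, dose_value in chosen:
            base.cases.append(TestCase(
                patient=patient_to_dict(neg_record(cls_name, dose_value)),
                expected_conforms=False,
                note=f"random non-recommended: {cls_name} {dose_value}"))
    return base


def run_test_base(kb: KnowledgeBase, base: TestBase,
                  ruleset: Optional[RuleSet] = None) -> list[str]:
    """Replay a test base; returns the list of failures (empty = all
    expectations met).  The verdict of a case expected to conform under
    relaxation level k is checked with the relaxable rules of gap <= k
    suppressed."""
    from .patient_model import patient_from_dict

    if ruleset is None:
        ruleset = compile_kb(kb)
    failures = []
    for i, case in enumerate(base.cases):
        record = prepare_record(patient_from_dict(case.patient), kb)
        from .matching import MatchContext, eval_condition
        ctx = MatchContext(record=record, kb=kb)
        fired = [r for r in ruleset.active_rules(case.expected_relaxation)
                 if eval_condition(r.condition, ctx)]
        conforms = not fired
        if conforms != case.expected_conforms:
            failures.append(
                f"case {i} ({case.note}): expected "
                f"conforms={case.expected_conforms}, got {conforms}")
    return failures
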