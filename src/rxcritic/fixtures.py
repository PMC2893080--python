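"""Built-in toy knowledge bases and patient scenarios.

Three small KBs exercise every part of the system without any external
data:

* ``diabetes_kb`` — the type-2-diabetes monotherapy worked example:
  metformin first-line, alpha-glucosidase inhibitor (AGI) second-line,
  applicable when the physician prescribes a monotherapy (diet + a single
  oral drug) and HbA1c <= 6.5%.  Its six (patient stage x proposal)
  scenarios form the reference critique matrix.
* ``statin_kb`` — a dyslipaemia fragment: simvastatin / pravastatin /
  atorvastatin first-line, rosuvastatin reserved for tolerance or efficacy
  problems with the other statins, and no drug treatment for patients over
  80 in primary prevention.  Small enough for full vector enumeration and
  decision-tree regeneration.
* ``generic_exercise_kb`` — a smoking-cessation-flavoured KB for the
  generic recommendations: a multi-code glinide class, a beta-blocker
  class for the no-two-drugs-of-one-class rule, and bupropion as the
  exception whose dose cannot be lowered (narrow therapeutic range).

Fixture expectations are regenerated, never hand-maintained: ``regen``
recomputes the critique expectations through the engine and rewrites the
YAML files shipped under ``rxcritic/data``; a test fails if the committed
files drift from what the current code produces.

The HbA1c threshold is written as an inclusive <= 6.5%; the source
guideline's prose ("lower than") and its rendered condition disagree, and
the inclusive reading matches the rendered form.
"""

from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .engine import critique
from .kb_model import KnowledgeBase, kb_from_dict, kb_to_yaml
from .patient_model import PatientRecord, load_patient, patient_from_dict

__all__ = [
    "diabetes_kb",
    "statin_kb",
    "generic_exercise_kb",
    "table1_scenarios",
    "random_small_kb",
    "random_history_doc",
    "FixtureSet",
    "build_fixtures",
    "regen",
    "data_dir",
    "check_drift",
]

CRITIQUE_DATE = "2009-12-01"


def data_dir() -> Path:
    return Path(__file__).parent / "data"


# --------------------------------------------------------------------------
# Diabetes monotherapy (the worked example)
# --------------------------------------------------------------------------

def diabetes_kb(generics: bool = False) -> KnowledgeBase:
    """Metformin first-line / AGI second-line monotherapy KB.

    With ``generics=False`` (the default, used by the reference critique
    matrix) the generic recommendations are disabled: preventing the
    represcription of failed treatments is their task, not the
    recommendation's, and the matrix isolates the recommendation.
    """
    doc = {
        "name": "diabetes_monotherapy",
        "drug_classes": {
            "metformin": ["A10BA02"],
            "agi": ["A10BF"],
            "sulfonamide": ["A10BB"],
            # no single ATC subtree covers the glinides: two codes
            "glinide": ["A10BX02", "A10BX03"],
            "glitazone": ["A10BG"],
            "oral_antidiabetic": ["A10B"],
        },
        "non_drugs": ["diet"],
        "attributes": {
            "HbA1c": {"type": "number", "grid": [6.0, 7.0]},
        },
        "recommendable_treatments": [
            {"name": "diet_metformin", "components": [
                {"non_drug": "diet"},
                {"drug": {"atc": "A10BA02", "inn": "metformin",
                          "dose": {"value": 850, "unit": "mg"},
                          "form": "tablet"}}]},
            {"name": "diet_agi", "components": [
                {"non_drug": "diet"},
                {"drug": {"atc": "A10BF01", "inn": "acarbose",
                          "dose": {"value": 300, "unit": "mg"},
                          "form": "tablet"}}]},
        ],
        "recommendations": [{
            "id": "monotherapy_choice",
            "type": "should_prescribe",
            "conditions": {"and": [
                {"therapeutic": {"scope": "proposed", "pattern": {
                    "components": [{"non_drug": "diet"},
                                   {"class": "oral_antidiabetic"}],
                    "cardinality": 1}}},
                {"clinical": ["HbA1c", "<=", 6.5]},
            ]},
            "lines": [
                [{"components": [{"non_drug": "diet"},
                                 {"class": "metformin"}]}],
                [{"components": [{"non_drug": "diet"}, {"class": "agi"}]}],
            ],
            "explanation_labels": {
                2: "AGI should be prescribed only as second-line treatment.",
                3: "Sulfonamides, glinides and glitazones are not recommended.",
            },
            "advice_labels": {
                1: "Guideline recommends metformin as first-line treatment.",
                2: "Guideline recommends metformin as first-line treatment, "
                   "and AGI as second-line.",
            },
        }],
        "generic": {
            "applicability": {i: ("full" if generics else "not_applicable")
                              for i in range(1, 9)},
            # intolerance of one oral antidiabetic says nothing about the
            # others: keep the umbrella class out of the class-intolerance rule
            "exceptions": {6: ["oral_antidiabetic"]},
        },
    }
    return kb_from_dict(doc)


def _table1_patient(stage: int, proposal: str) -> dict:
    """One cell of the six-situation critique matrix, as a patient doc."""
    proposals = {
        "metformin": {"drug": {"atc": "A10BA02", "inn": "metformin",
                               "dose": {"value": 850, "unit": "mg"},
                               "form": "tablet"}},
        "agi": {"drug": {"atc": "A10BF01", "inn": "acarbose",
                         "dose": {"value": 300, "unit": "mg"},
                         "form": "tablet"}},
        "other": {"drug": {"atc": "A10BB01", "inn": "glibenclamide",
                           "dose": {"value": 5, "unit": "mg"},
                           "form": "tablet"}},
    }
    doc: dict = {
        "biological": {"HbA1c": 6.2},
        "critique_date": CRITIQUE_DATE,
        "proposed": {"components": [{"non_drug": "diet"},
                                    proposals[proposal]]},
    }
    if stage == 2:  # first-line metformin already failed
        doc["history"] = [{
            "status": "past", "efficacy": "ineffective",
            "start": "2009-01-01", "end": "2009-06-01",
            "components": [
                {"non_drug": "diet"},
                {"drug": {"atc": "A10BA02", "inn": "metformin",
                          "dose": {"value": 850, "unit": "mg"},
                          "form": "tablet",
                          "tolerance": "well_tolerated"}}]}]
    return doc


def table1_scenarios() -> dict[str, dict]:
    """The six (stage x proposal) scenarios of the critique matrix."""
    return {f"stage{stage}_{proposal}": _table1_patient(stage, proposal)
            for stage in (1, 2)
            for proposal in ("metformin", "agi", "other")}


# --------------------------------------------------------------------------
# Dyslipaemia statin fragment (verification fixture)
# --------------------------------------------------------------------------

def statin_kb() -> KnowledgeBase:
    doc = {
        "name": "dyslipaemia_statins",
        "drug_classes": {
            "simvastatin": ["C10AA01"],
            "pravastatin": ["C10AA03"],
            "atorvastatin": ["C10AA05"],
            "rosuvastatin": ["C10AA07"],
            "statin": ["C10AA"],
            "fibrate": ["C10AB"],
            "lipid_lowering": ["C10"],
        },
        "attributes": {
            "age": {"type": "number", "grid": [75, 85]},
            "prevention": {"type": "string", "grid": ["primary", "secondary"]},
        },
        "recommendable_treatments": [
            {"name": "simvastatin", "components": [
                {"drug": {"atc": "C10AA01", "inn": "simvastatin",
                          "dose": {"value": 20, "unit": "mg"}}}]},
            {"name": "pravastatin", "components": [
                {"drug": {"atc": "C10AA03", "inn": "pravastatin",
                          "dose": {"value": 20, "unit": "mg"}}}]},
            {"name": "atorvastatin", "components": [
                {"drug": {"atc": "C10AA05", "inn": "atorvastatin",
                          "dose": {"value": 10, "unit": "mg"}}}]},
            {"name": "rosuvastatin", "components": [
                {"drug": {"atc": "C10AA07", "inn": "rosuvastatin",
                          "dose": {"value": 5, "unit": "mg"}}}]},
        ],
        "recommendations": [
            {
                "id": "statin_lines",
                "type": "should_prescribe",
                "conditions": {"not": {"and": [
                    {"clinical": ["age", ">", 80]},
                    {"clinical": ["prevention", "=", "primary"]},
                ]}},
                "lines": [
                    [{"components": [{"class": "simvastatin"}]},
                     {"components": [{"class": "pravastatin"}]},
                     {"components": [{"class": "atorvastatin"}]}],
                    [{"components": [{"class": "rosuvastatin"}]}],
                ],
                "explanation_labels": {
                    2: "Rosuvastatin should only be used in case of "
                       "tolerance or efficacy problems with other statins.",
                    3: "Only statins are recommended as first-line drug "
                       "treatment.",
                },
                "advice_labels": {
                    1: "Guideline recommends simvastatin, pravastatin or "
                       "atorvastatin as first-line treatment.",
                    2: "Guideline recommends rosuvastatin as second-line "
                       "treatment.",
                },
            },
            {
                "id": "no_treatment_over_80_primary",
                "type": "should_not_prescribe",
                "conditions": {"and": [
                    {"clinical": ["age", ">", 80]},
                    {"clinical": ["prevention", "=", "primary"]},
                ]},
                "forbidden": {"components": [{"class": "lipid_lowering"},
                                             "any"]},
                "criticism_label": "It is not recommended to start a "
                                   "lipid-lowering treatment for patients "
                                   "older than 80, in primary prevention.",
            },
        ],
        "generic": {
            "applicability": {1: "not_applicable", 2: "not_applicable",
                              3: "not_applicable", 4: "not_applicable",
                              5: "full", 6: "full", 7: "full", 8: "full"},
            # intolerance is tracked per statin, not for the umbrella
            # classes: simvastatin intolerance does not forbid atorvastatin
            "exceptions": {6: ["statin", "fibrate", "lipid_lowering"]},
        },
    }
    return kb_from_dict(doc)


# --------------------------------------------------------------------------
# Generic-recommendation exercise KB
# --------------------------------------------------------------------------

def generic_exercise_kb() -> KnowledgeBase:
    doc = {
        "name": "generic_exercise",
        "drug_classes": {
            "nicotine_replacement": ["N07BA01"],
            "bupropion": ["N06AX12"],
            "beta_blocker": ["C07A"],
            "glinide": ["A10BX02", "A10BX03"],
            "metformin": ["A10BA02"],
        },
        "recommendable_treatments": [
            {"name": "nicotine_patch", "components": [
                {"drug": {"atc": "N07BA01", "inn": "nicotine",
                          "dose": {"value": 15, "unit": "mg"},
                          "form": "patch"}}]},
            {"name": "bupropion_150", "components": [
                {"drug": {"atc": "N06AX12", "inn": "bupropion",
                          "dose": {"value": 150, "unit": "mg"},
                          "form": "tablet"}}]},
        ],
        "recommendations": [{
            "id": "cessation_support",
            "type": "should_prescribe",
            "lines": [
                [{"components": [{"class": "nicotine_replacement"}]}],
                [{"components": [{"class": "bupropion"}]}],
            ],
            "explanation_labels": {
                2: "Bupropion is a second-line aid.",
                3: "Other drugs are not recommended for smoking cessation.",
            },
            "advice_labels": {
                1: "Guideline recommends nicotine replacement first.",
                2: "Guideline recommends nicotine replacement first, "
                   "then bupropion.",
            },
        }],
        "generic": {
            # all eight generic recommendations apply in full...
            "applicability": {i: "full" for i in range(1, 9)},
            # ...except that bupropion's dose cannot be lowered (narrow
            # therapeutic range), so it is exempt from the dose-decrease rule
            "exceptions": {4: ["bupropion"]},
        },
    }
    return kb_from_dict(doc)


# --------------------------------------------------------------------------
# Randomized small KBs and histories (property-test material)
# --------------------------------------------------------------------------

_ATC_ROOTS = ("A02B", "A10B", "C03C", "C07A", "C09A", "N06A")


def random_small_kb(rng: random.Random, max_classes: int = 4,
                    max_lines: int = 3) -> KnowledgeBase:
    """A seeded random should_prescribe KB: up to ``max_classes`` drug
    classes spread over 1-2 recommendations of 1..``max_lines`` lines,
    generics disabled (the recommendation semantics are the subject)."""
    n_classes = rng.randint(2, max_classes)
    roots = rng.sample(_ATC_ROOTS, n_classes)
    classes = {f"cls{i}": [roots[i]] for i in range(n_classes)}
    doc: dict = {
        "name": f"random_kb_{rng.randrange(1 << 30)}",
        "drug_classes": classes,
        "attributes": {"severity": {"type": "number", "grid": [1, 5]}},
        "recommendable_treatments": [
            {"name": f"t_cls{i}", "components": [
                {"drug": {"atc": f"{roots[i]}A{i:02d}", "inn": f"drug{i}",
                          "dose": {"value": 10 * (i + 1), "unit": "mg"}}}]}
            for i in range(n_classes)],
        "recommendations": [],
        "generic": {"applicability": {i: "not_applicable"
                                      for i in range(1, 9)}},
    }
    n_recs = rng.randint(1, 2)
    available = list(range(n_classes))
    for r in range(n_recs):
        n = rng.randint(1, min(max_lines, len(available)))
        line_classes = rng.sample(available, n)
        rec = {
            "id": f"rec{r}",
            "type": "should_prescribe",
            "lines": [[{"components": [{"class": f"cls{i}"}]}]
                      for i in line_classes],
            "explanation_labels": {y: f"[rec{r}] line-{y} proposal."
                                   for y in range(2, n + 2)},
            "advice_labels": {x: f"[rec{r}] stage-{x} advice."
                              for x in range(1, n + 1)},
        }
        if rng.random() < 0.4:
            rec["conditions"] = {"clinical": ["severity", "<=", 3]}
        doc["recommendations"].append(rec)
    return kb_from_dict(doc)


def random_history_doc(rng: random.Random, kb: KnowledgeBase,
                       max_len: int = 3) -> dict:
    """A seeded random patient document for the given KB: a short history
    of class drugs with random outcomes, plus a random proposal."""
    class_names = list(kb.drug_classes)
    def drug(i: int, tolerance: Optional[str]) -> dict:
        cls = kb.drug_classes[class_names[i]]
        d = {"atc": cls.atc_codes[0], "inn": f"drug{i}",
             "dose": {"value": 10 * (i + 1), "unit": "mg"}}
        if tolerance:
            d["tolerance"] = tolerance
        return d
    history = []
    start = dt.date(2007, 1, 1)
    for j in range(rng.randint(0, max_len)):
        i = rng.randrange(len(class_names))
        history.append({
            "status": "past",
            "efficacy": rng.choice(["ineffective", "effective", "unknown"]),
            "start": (start + dt.timedelta(days=200 * j)).isoformat(),
            "end": (start + dt.timedelta(days=200 * j + 150)).isoformat(),
            "components": [{"drug": drug(i, rng.choice(
                ["well_tolerated", "poorly_tolerated", "unknown"]))}],
        })
    proposed_i = rng.randrange(len(class_names))
    return {
        "clinical": {"severity": rng.choice([1, 5])},
        "critique_date": "2009-12-01",
        "history": history,
        "proposed": {"components": [{"drug": drug(proposed_i, None)}]},
    }


# --------------------------------------------------------------------------
# Fixture set and regeneration
# --------------------------------------------------------------------------

@dataclass
class FixtureSet:
    kbs: dict[str, KnowledgeBase] = field(default_factory=dict)
    scenarios: dict[str, dict] = field(default_factory=dict)
    expected: dict[str, dict] = field(default_factory=dict)


def build_fixtures(seed: int = 0) -> FixtureSet:
    """Assemble the fixture KBs, the critique-matrix scenarios, and their
    engine-computed expected results (never hand-written)."""
    fs = FixtureSet()
    fs.kbs = {"diabetes": diabetes_kb(), "statin": statin_kb(),
              "generic_exercise": generic_exercise_kb()}
    fs.scenarios = table1_scenarios()
    kb = fs.kbs["diabetes"]
    for name, doc in fs.scenarios.items():
        res = critique(patient_from_dict(doc), kb)
        fs.expected[name] = {"conforms": res.conforms,
                             "text": res.composed_text}
    rng = random.Random(seed)
    for i in range(3):
        kb_name = rng.choice(["diabetes", "statin"])
        # random scenarios exercise loading; no expectations attached
        fs.scenarios[f"random_{i}_{kb_name}"] = random_history_doc(
            rng, fs.kbs[kb_name])
    return fs


def _render_files(seed: int = 0) -> dict[str, str]:
    fs = build_fixtures(seed)
    dump = lambda d: yaml.safe_dump(d, sort_keys=False, allow_unicode=True)
    files = {f"{name}.yaml": kb_to_yaml(kb) for name, kb in fs.kbs.items()}
    files["table1_patients.yaml"] = dump(table1_scenarios())
    files["expected_critiques.yaml"] = dump(
        {k: fs.expected[k] for k in sorted(fs.expected)})
    return files


def regen(target: Optional[Path] = None, seed: int = 0) -> list[str]:
    """Rewrite the shipped fixture files; returns the file names written."""
    target = Path(target) if target else data_dir()
    target.mkdir(parents=True, exist_ok=True)
    files = _render_files(seed)
    for name, text in files.items():
        (target / name).write_text(text, encoding="utf-8")
    return sorted(files)


def check_drift(seed: int = 0) -> list[str]:
    """Compare the committed fixture files against a fresh regeneration;
    returns the names of files that differ (empty = no drift)."""
    drifted = []
    for name, text in _render_files(seed).items():
        path = data_dir() / name
        if not path.exists() or path.read_text(encoding="utf-8") != text:
            drifted.append(name)
    return sorted(drifted)
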