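"""Patient record, therapeutic history, and the data-enriching component.

The critiquing engine works on a *patient record*: clinical attributes,
biological results, an ordered therapeutic history (past and current
treatments with their outcomes — per-drug tolerance, per-treatment
efficacy), and exactly one treatment proposed by the physician.

The data-enriching component computes derived attributes (BMI), relative
posologies (has the proposed prescription increased or lowered the dose of
a drug of the current treatment, changed its form, or switched the INN?),
groups the proposed drugs by indication (dose-dependent for drugs such as
aspirin; a drug with several indications is duplicated into every group),
and normalizes outcomes: a treatment that is both ineffective and poorly
tolerated is handled through the poor-tolerance pathway only, because low
adherence under poor tolerance makes the efficacy unevaluable.
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Union

import yaml

from .kb_model import (
    CHANGE_KINDS,
    EFFICACY_VALUES,
    STATUS_VALUES,
    TOLERANCE_VALUES,
    KnowledgeBase,
    NonDrug,
    Quantity,
    TreatmentTemplate,
)

__all__ = [
    "DrugLine",
    "Treatment",
    "PatientRecord",
    "IndicationGroups",
    "load_patient",
    "patient_from_dict",
    "patient_to_dict",
    "enrich",
    "assign_indications",
    "normalize_outcomes",
    "treatment_from_template",
]


@dataclass
class DrugLine:
    """One drug of a treatment, with its tolerance for this patient."""

    atc_code: str
    inn: str
    dose: Optional[Quantity] = None
    form: Optional[str] = None
    tolerance: str = "unknown"


@dataclass
class Treatment:
    """A treatment: drug lines plus optional non-drug components (diet...).

    ``efficacy_masked`` is set by :func:`normalize_outcomes`; matching then
    sees the efficacy as unknown while the tolerance values stay intact.
    ``change_flags`` is filled by :func:`enrich` on the proposed treatment
    (relative posology versus the current treatment).
    """

    components: list[Union[DrugLine, NonDrug]] = field(default_factory=list)
    status: str = "past"
    efficacy: str = "unknown"
    start_date: Optional[dt.date] = None
    end_date: Optional[dt.date] = None
    efficacy_masked: bool = False
    change_flags: frozenset = frozenset()
    audit_notes: list[str] = field(default_factory=list)

    @property
    def drugs(self) -> list[DrugLine]:
        return [c for c in self.components if isinstance(c, DrugLine)]

    @property
    def non_drug_names(self) -> set[str]:
        return {c.name for c in self.components if isinstance(c, NonDrug)}

    def visible_efficacy(self) -> str:
        return "unknown" if self.efficacy_masked else self.efficacy

    def is_failed(self) -> bool:
        """Ineffective or containing a poorly tolerated drug (the "failed
        treatment" test of the patient-stage conditions)."""
        return (self.visible_efficacy() == "ineffective" or
                any(d.tolerance == "poorly_tolerated" for d in self.drugs))


@dataclass
class PatientRecord:
    clinical: dict[str, Any] = field(default_factory=dict)
    biological: dict[str, Any] = field(default_factory=dict)
    history: list[Treatment] = field(default_factory=list)
    proposed: Optional[Treatment] = None
    critique_date: Optional[dt.date] = None
    notes: list[str] = field(default_factory=list)

    def attribute(self, name: str) -> Any:
        """Clinical attributes and biological results share one namespace."""
        if name in self.clinical:
            return self.clinical[name]
        return self.biological.get(name)

    def current(self) -> Optional[Treatment]:
        for t in self.history:
            if t.status == "current":
                return t
        return None

    def ordered_history(self) -> list[Treatment]:
        """History sorted by start date; ties keep record order (stable)."""
        return sorted(self.history,
                      key=lambda t: (t.start_date or dt.date.min,))


# --------------------------------------------------------------------------
# Parsing / serialization
# --------------------------------------------------------------------------

def _parse_date(v: Any) -> Optional[dt.date]:
    if v is None or isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def _parse_quantity(d: Any) -> Optional[Quantity]:
    if d is None:
        return None
    q = Quantity(value=float(d["value"]), unit=str(d["unit"]),
                 per=d.get("per", "day"))
    if q.value <= 0:
        raise ValueError(f"dose must be positive, got {q.value}")
    return q


def _parse_treatment(d: Mapping, default_status: str = "past") -> Treatment:
    comps: list[Union[DrugLine, NonDrug]] = []
    for cd in d.get("components", []) or []:
        if "non_drug" in cd:
            comps.append(NonDrug(str(cd["non_drug"])))
        else:
            dd = cd["drug"] if "drug" in cd else cd
            tol = dd.get("tolerance", "unknown")
            if tol not in TOLERANCE_VALUES + ("unknown",):
                raise ValueError(f"unknown tolerance {tol!r}")
            comps.append(DrugLine(
                atc_code=str(dd.get("atc", "")), inn=str(dd.get("inn", "")),
                dose=_parse_quantity(dd.get("dose")), form=dd.get("form"),
                tolerance=tol))
    status = d.get("status", default_status)
    if status not in STATUS_VALUES:
        raise ValueError(f"unknown status {status!r}")
    eff = d.get("efficacy", "unknown")
    if eff not in EFFICACY_VALUES + ("unknown",):
        raise ValueError(f"unknown efficacy {eff!r}")
    t = Treatment(components=comps, status=status, efficacy=eff,
                  start_date=_parse_date(d.get("start")),
                  end_date=_parse_date(d.get("end")))
    if t.status == "past" and t.end_date is None and t.start_date is not None:
        raise ValueError("past treatments need an end date")
    return t


def patient_from_dict(doc: Mapping) -> PatientRecord:
    history = [_parse_treatment(td) for td in doc.get("history", []) or []]
    proposed = None
    if doc.get("proposed") is not None:
        proposed = _parse_treatment(doc["proposed"], default_status="proposed")
        proposed.status = "proposed"
    n_proposed = sum(1 for t in history if t.status == "proposed")
    if n_proposed:
        raise ValueError("the proposed treatment goes in 'proposed', not history")
    return PatientRecord(
        clinical=dict(doc.get("clinical") or {}),
        biological=dict(doc.get("biological") or {}),
        history=history, proposed=proposed,
        critique_date=_parse_date(doc.get("critique_date")))


def load_patient(source: Union[str, Mapping]) -> PatientRecord:
    """Load a patient record from YAML text, a ``.yaml`` path or a dict."""
    if isinstance(source, Mapping):
        return patient_from_dict(source)
    text = str(source)
    if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()
    return patient_from_dict(yaml.safe_load(text))


def _treatment_to_dict(t: Treatment) -> dict:
    comps: list[Any] = []
    for c in t.components:
        if isinstance(c, NonDrug):
            comps.append({"non_drug": c.name})
        else:
            dd: dict[str, Any] = {"atc": c.atc_code, "inn": c.inn}
            if c.dose is not None:
                dd["dose"] = {"value": c.dose.value, "unit": c.dose.unit} | (
                    {"per": c.dose.per} if c.dose.per != "day" else {})
            if c.form is not None:
                dd["form"] = c.form
            if c.tolerance != "unknown":
                dd["tolerance"] = c.tolerance
            comps.append({"drug": dd})
    d: dict[str, Any] = {"components": comps, "status": t.status}
    if t.efficacy != "unknown":
        d["efficacy"] = t.efficacy
    if t.start_date is not None:
        d["start"] = t.start_date.isoformat()
    if t.end_date is not None:
        d["end"] = t.end_date.isoformat()
    return d


def patient_to_dict(record: PatientRecord) -> dict:
    doc: dict[str, Any] = {}
    if record.clinical:
        doc["clinical"] = dict(record.clinical)
    if record.biological:
        doc["biological"] = dict(record.biological)
    if record.critique_date is not None:
        doc["critique_date"] = record.critique_date.isoformat()
    if record.history:
        doc["history"] = [_treatment_to_dict(t) for t in record.history]
    if record.proposed is not None:
        doc["proposed"] = _treatment_to_dict(record.proposed)
    return doc


def treatment_from_template(template: TreatmentTemplate,
                            status: str = "proposed") -> Treatment:
    """Instantiate a recommendable-treatment template as a concrete
    treatment (used when the engine substitutes candidate suggestions)."""
    comps: list[Union[DrugLine, NonDrug]] = []
    for c in template.components:
        if isinstance(c, NonDrug):
            comps.append(c)
        else:
            comps.append(DrugLine(atc_code=c.atc_code, inn=c.inn,
                                  dose=c.dose, form=c.form,
                                  tolerance="unknown"))
    return Treatment(components=comps, status=status)


# --------------------------------------------------------------------------
# Data enriching
# --------------------------------------------------------------------------

def _compute_change_flags(proposed: Treatment,
                          current: Optional[Treatment]) -> tuple[frozenset, list[str]]:
    """Relative posology of the proposal versus the current treatment.

    Per-INN comparison: a shared INN with a higher/lower dose yields
    dose_increase/dose_decrease, a different form yields form_change; any
    difference in the INN sets yields inn_change.  Dose comparison requires
    identical units and periods (no unit conversion); a mismatch is noted
    and produces no flag.
    """
    notes: list[str] = []
    if current is None or proposed is None:
        return frozenset(), notes
    flags: set[str] = set()
    cur = {d.inn: d for d in current.drugs}
    prop = {d.inn: d for d in proposed.drugs}
    if set(cur) != set(prop):
        flags.add("inn_change")
    for inn in set(cur) & set(prop):
        a, b = cur[inn], prop[inn]
        if a.dose is not None and b.dose is not None:
            if (a.dose.unit, a.dose.per) != (b.dose.unit, b.dose.per):
                notes.append(f"dose units differ for {inn} "
                             f"({a.dose.unit}/{a.dose.per} vs "
                             f"{b.dose.unit}/{b.dose.per}); no dose comparison")
            elif b.dose.value > a.dose.value:
                flags.add("dose_increase")
            elif b.dose.value < a.dose.value:
                flags.add("dose_decrease")
        if a.form is not None and b.form is not None and a.form != b.form:
            flags.add("form_change")
    return frozenset(flags), notes


def enrich(record: PatientRecord, kb: KnowledgeBase) -> PatientRecord:
    """Return an enriched copy of the record (the input is not modified).

    Adds BMI = weight / height**2 when height (m) and weight (kg) are
    present (missing data is noted, never fatal) and computes the proposed
    treatment's relative-posology flags.  Idempotent: derived values are
    recomputed from the base fields each call.
    """
    out = copy.deepcopy(record)
    out.notes = [n for n in out.notes if not n.startswith("enrich:")]
    height = out.attribute("height")
    weight = out.attribute("weight")
    if height and weight:
        out.clinical["BMI"] = round(float(weight) / float(height) ** 2, 2)
    else:
        out.clinical.pop("BMI", None)
        # only worth a note when BMI could matter: partial data, or the
        # KB actually declares the attribute
        if (height is None) != (weight is None) or "BMI" in kb.attributes:
            out.notes.append("enrich: BMI not computable "
                             "(height or weight missing)")
    if out.proposed is not None:
        flags, notes = _compute_change_flags(out.proposed, out.current())
        out.proposed.change_flags = flags
        out.notes.extend("enrich: " + n for n in notes)
    return out


@dataclass
class IndicationGroups:
    """Proposed drugs regrouped by indication; the critique runs once per
    group.  ``unmapped`` lists drugs with no (class, dose) entry — they are
    excluded with a warning rather than silently dropped."""

    groups: dict[str, Treatment] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def items(self):
        return self.groups.items()


def _dose_in_range(rule, dose: Optional[Quantity]) -> bool:
    if rule.dose_min is None and rule.dose_max is None:
        return True
    if dose is None or (rule.unit is not None and dose.unit != rule.unit):
        return False
    if rule.dose_min is not None and dose.value < rule.dose_min:
        return False
    if rule.dose_max is not None and dose.value > rule.dose_max:
        return False
    return True


def assign_indications(record: PatientRecord, kb: KnowledgeBase) -> IndicationGroups:
    """Assign each proposed drug to >= 1 indication via the KB's
    (drug class, dose range) map, duplicating drugs with several
    indications into every matching group.

    With an empty indication map the whole proposal forms one "default"
    group, so single-indication KBs need no map at all.
    """
    out = IndicationGroups()
    if record.proposed is None:
        return out
    if not kb.indication_map:
        out.groups["default"] = record.proposed
        return out
    non_drugs = [c for c in record.proposed.components if isinstance(c, NonDrug)]
    assignments: dict[str, list[DrugLine]] = {}
    for drug in record.proposed.drugs:
        found = False
        for rule in kb.indication_map:
            cls = kb.drug_classes.get(rule.drug_class)
            if cls is None or not cls.contains(drug.atc_code):
                continue
            if _dose_in_range(rule, drug.dose):
                assignments.setdefault(rule.indication, []).append(drug)
                found = True
        if not found:
            out.unmapped.append(drug.inn or drug.atc_code)
    for indication, drugs in assignments.items():
        t = Treatment(components=list(non_drugs) + list(drugs),
                      status="proposed", efficacy=record.proposed.efficacy,
                      change_flags=record.proposed.change_flags)
        out.groups[indication] = t
    return out


def normalize_outcomes(record: PatientRecord) -> PatientRecord:
    """Apply the dual-failure convention: a treatment that is both
    ineffective and poorly tolerated is matched through the poor-tolerance
    pathway only (its efficacy is masked to unknown for matching; the
    stored efficacy and all tolerance values are untouched)."""
    out = copy.deepcopy(record)
    for t in out.history + ([out.proposed] if out.proposed else []):
        poorly = any(d.tolerance == "poorly_tolerated" for d in t.drugs)
        if t.efficacy == "ineffective" and poorly:
            if not t.efficacy_masked:
                t.efficacy_masked = True
                t.audit_notes.append(
                    "dual failure (ineffective + poorly tolerated): "
                    "poor-tolerance pathway applies; efficacy masked for matching")
        else:
            t.efficacy_masked = False
    return out
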