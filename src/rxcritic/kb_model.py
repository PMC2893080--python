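"""Knowledge-base schema: drug classes, treatment patterns, recommendations.

A knowledge base (KB) captures the therapeutic recommendations of one
clinical practice guideline in a declarative YAML document.  Its building
blocks are:

* **drug classes** — named sets of ATC codes (the ATC classification is
  hierarchical, so a class may sit at any level: ``C07A`` covers every
  beta-blocking agent, ``A10BA02`` is metformin alone).  A drug belongs to
  a class iff one of the class codes is a prefix of the drug's full code;
  classes that cannot be expressed as a single subtree (e.g. the glinides)
  simply list several codes.
* **treatment patterns** — granularity-flexible queries over treatments
  ("any bitherapy", "metformin with poor tolerance", "a dose increase").
  Patterns are matched existentially against the therapeutic history; they
  are never concrete treatments themselves.
* **recommendations** — three types: *one should prescribe* (ordered lines
  of treatment with per-line criticism labels), *one should not prescribe*
  (a forbidden pattern), and *treatments of increasing power* (ordered
  power levels).
* **generic-recommendation configuration** — applicability and exceptions
  for the eight guideline-independent recommendations (see
  :mod:`rxcritic.rule_compiler`).

The loader validates the whole document and reports **every** problem it
finds, not just the first, with a location path for each.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "ATC_CODE_RE",
    "Quantity",
    "DoseConstraint",
    "DrugClass",
    "DrugSpec",
    "NonDrug",
    "TreatmentTemplate",
    "ComponentPattern",
    "TreatmentPattern",
    "ClinicalPredicate",
    "Cond",
    "AND",
    "OR",
    "NOT",
    "CLIN",
    "THER",
    "NATIVE",
    "TRUE",
    "Recommendation",
    "GenericRecConfig",
    "IndicationRule",
    "AttributeDecl",
    "KnowledgeBase",
    "KBValidationError",
    "load_kb",
    "kb_from_dict",
    "kb_to_dict",
    "kb_to_yaml",
    "validate_cross_references",
    "CrossRefReport",
]

# Proper ATC structure: letter, 2 digits, letter, letter, 2 digits — any prefix.
ATC_CODE_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")

TOLERANCE_VALUES = ("well_tolerated", "poorly_tolerated")
EFFICACY_VALUES = ("ineffective", "effective", "too_effective")
STATUS_VALUES = ("past", "current", "proposed")
CHANGE_KINDS = ("dose_increase", "dose_decrease", "form_change", "inn_change")
REC_TYPES = ("should_prescribe", "should_not_prescribe", "increasing_power")
GENERIC_IDS = tuple(range(1, 9))
APPLICABILITY_VALUES = ("full", "partial", "not_applicable")

_CMP_ALIASES = {
    "=": "=", "==": "=", "≠": "!=", "!=": "!=",
    "<": "<", "≤": "<=", "<=": "<=", ">": ">", "≥": ">=", ">=": ">=",
    "in": "in",
}
COMPARATORS = ("=", "!=", "<", "<=", ">", ">=")


# --------------------------------------------------------------------------
# Elementary value objects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Quantity:
    """A dose: numeric value, unit, and period (per day or per intake)."""

    value: float
    unit: str
    per: str = "day"


@dataclass(frozen=True)
class DoseConstraint:
    """Comparator applied to a component's dose, e.g. ``>= 1000 mg/day``."""

    op: str
    quantity: Quantity


@dataclass(frozen=True)
class DrugClass:
    """A named pharmaco-therapeutic class: one or more ATC codes."""

    name: str
    atc_codes: tuple[str, ...]

    def contains(self, atc_code: str) -> bool:
        """ATC membership by hierarchical prefix."""
        return any(atc_code.startswith(code) for code in self.atc_codes)


@dataclass(frozen=True)
class DrugSpec:
    """A concrete drug inside a recommendable-treatment template."""

    atc_code: str
    inn: str
    dose: Optional[Quantity] = None
    form: Optional[str] = None


@dataclass(frozen=True)
class NonDrug:
    """A non-drug treatment component, e.g. diet."""

    name: str


@dataclass(frozen=True)
class TreatmentTemplate:
    """A concrete treatment the guideline can recommend (suggestion pool)."""

    name: str
    components: tuple[Union[DrugSpec, NonDrug], ...]

    @property
    def drugs(self) -> tuple[DrugSpec, ...]:
        return tuple(c for c in self.components if isinstance(c, DrugSpec))


# --------------------------------------------------------------------------
# Patterns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentPattern:
    """One slot of a treatment pattern.

    ``kind`` is ``drug_class_ref`` (a drug of a named class, optionally
    constrained by dose/form/tolerance), ``non_drug`` (e.g. diet), or
    ``any_wildcard`` (absorbs between ``min_repeat`` and ``max_repeat``
    leftover components; ``max_repeat=None`` means unbounded).
    """

    kind: str
    drug_class: Optional[str] = None
    non_drug: Optional[str] = None
    dose: Optional[DoseConstraint] = None
    form: Optional[str] = None
    tolerance: Optional[str] = None
    min_repeat: int = 0
    max_repeat: Optional[int] = None


ANY = ComponentPattern(kind="any_wildcard")


@dataclass(frozen=True)
class TreatmentPattern:
    """A query over treatments, at any level of granularity.

    ``failed`` is the compiler's overlay for "ineffective or poorly
    tolerated" (evaluated after outcome normalization); ``changes`` matches
    a treatment whose computed relative-posology flags intersect the given
    set; ``cardinality`` counts drug components only (diet is excluded, so
    "diet + one oral drug" is a monotherapy); ``window_days`` bounds the
    treatment's end date relative to the critique date.
    """

    components: tuple[ComponentPattern, ...] = ()
    status: Optional[str] = None
    efficacy: Optional[str] = None
    failed: Optional[bool] = None
    changes: frozenset = frozenset()
    cardinality: Optional[int] = None
    overall_tolerance: Optional[str] = None
    window_days: Optional[int] = None


@dataclass(frozen=True)
class ClinicalPredicate:
    """(attribute, operator, value) triplet, e.g. (age, <, 75)."""

    attribute: str
    op: str
    value: Any


# --------------------------------------------------------------------------
# Condition expressions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Cond:
    """A node of a nested condition expression.

    kinds: ``and``/``or``/``not`` (logical), ``clinical`` (a predicate),
    ``therapeutic`` (a treatment pattern with an evaluation scope:
    ``proposed`` tests only the physician's proposal, ``history`` quantifies
    existentially over past and current treatments, ``any`` over both),
    ``native`` (a named built-in test with parameters, used by compiled
    generic rules), and ``true`` (neutral element).
    """

    kind: str
    children: tuple["Cond", ...] = ()
    predicate: Optional[ClinicalPredicate] = None
    pattern: Optional[TreatmentPattern] = None
    scope: str = "any"
    native: Optional[str] = None
    params: tuple = ()


TRUE = Cond(kind="true")


def AND(*conds: Cond) -> Cond:
    conds = tuple(c for c in conds if c.kind != "true")
    if not conds:
        return TRUE
    if len(conds) == 1:
        return conds[0]
    return Cond(kind="and", children=conds)


def OR(*conds: Cond) -> Cond:
    if len(conds) == 1:
        return conds[0]
    return Cond(kind="or", children=tuple(conds))


def NOT(cond: Cond) -> Cond:
    return Cond(kind="not", children=(cond,))


def CLIN(attribute: str, op: str, value: Any) -> Cond:
    return Cond(kind="clinical",
                predicate=ClinicalPredicate(attribute, _CMP_ALIASES.get(op, op), value))


def THER(pattern: TreatmentPattern, scope: str = "any") -> Cond:
    return Cond(kind="therapeutic", pattern=pattern, scope=scope)


def NATIVE(name: str, **params: Any) -> Cond:
    return Cond(kind="native", native=name, params=tuple(sorted(params.items())))


# --------------------------------------------------------------------------
# Recommendations and KB
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Recommendation:
    """One structured guideline recommendation.

    For ``should_prescribe``, ``lines[i]`` holds the patterns of treatment
    line i+1; line N+1 ("any other treatment") is implicit and carries only
    an explanation label.  ``explanation_labels`` are keyed by the line of
    the *proposed* treatment (2..N+1), ``advice_labels`` by the line the
    *patient* is at (1..N); the criticism shown to the physician is the
    concatenation explanation + advice + reference.  For
    ``increasing_power``, ``lines`` are power levels ordered by increasing
    power (``lines[0]`` holds the least powerful treatments).
    ``should_not_prescribe`` carries a single ``forbidden`` pattern and a
    plain ``criticism_label``.
    """

    id: str
    rec_type: str
    conditions: Cond = TRUE
    lines: tuple[tuple[TreatmentPattern, ...], ...] = ()
    forbidden: Optional[TreatmentPattern] = None
    explanation_labels: Mapping[int, str] = field(default_factory=dict)
    advice_labels: Mapping[int, str] = field(default_factory=dict)
    reference_label: str = ""
    criticism_label: str = ""

    @property
    def n_lines(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class GenericRecConfig:
    """Per-KB configuration of the eight generic recommendations.

    ``applicability`` maps id 1..8 to full / partial / not_applicable
    (default: full — generic recommendations apply unless stated
    otherwise).  ``exceptions`` exempts named drug classes or recommendable
    treatments from a recommendation's scope (e.g. bupropion's dose cannot
    be lowered).  ``restrict_to`` holds, for *partial* applicability, the
    drug-class subset the recommendation is limited to.  ``labels``
    overrides the default criticism texts ("{name}" interpolates the class
    or treatment name).
    """

    applicability: Mapping[int, str] = field(default_factory=dict)
    exceptions: Mapping[int, frozenset] = field(default_factory=dict)
    restrict_to: Mapping[int, frozenset] = field(default_factory=dict)
    labels: Mapping[int, str] = field(default_factory=dict)

    def applies(self, gid: int) -> str:
        return self.applicability.get(gid, "full")


@dataclass(frozen=True)
class IndicationRule:
    """(drug class, dose range) -> indication, for prescription grouping."""

    drug_class: str
    indication: str
    dose_min: Optional[float] = None
    dose_max: Optional[float] = None
    unit: Optional[str] = None


@dataclass(frozen=True)
class AttributeDecl:
    """A clinical/biological attribute: value type plus, for the
    quasi-exhaustive verification, a finite grid of representative values."""

    name: str
    vtype: str = "number"
    grid: Optional[tuple] = None


@dataclass(frozen=True)
class KnowledgeBase:
    name: str
    drug_classes: Mapping[str, DrugClass] = field(default_factory=dict)
    non_drugs: tuple[str, ...] = ()
    recommendable_treatments: tuple[TreatmentTemplate, ...] = ()
    recommendations: tuple[Recommendation, ...] = ()
    generic: GenericRecConfig = field(default_factory=GenericRecConfig)
    indication_map: tuple[IndicationRule, ...] = ()
    attributes: Mapping[str, AttributeDecl] = field(default_factory=dict)

    def drug_class_of(self, atc_code: str) -> list[str]:
        """Names of every declared class containing the given ATC code."""
        return [n for n, c in self.drug_classes.items() if c.contains(atc_code)]

    def template(self, name: str) -> TreatmentTemplate:
        for t in self.recommendable_treatments:
            if t.name == name:
                return t
        raise KeyError(name)


class KBValidationError(ValueError):
    """Raised by load_kb; carries the complete list of problems found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("knowledge base invalid:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

class _Parser:
    """Error-collecting parser from the YAML mapping to the dataclasses."""

    def __init__(self) -> None:
        self.errors: list[str] = []
        self.class_names: set[str] = set()
        self.non_drugs: set[str] = set()
        self.attributes: dict[str, AttributeDecl] = {}

    def err(self, where: str, msg: str) -> None:
        self.errors.append(f"{where}: {msg}")

    # -- leaves ------------------------------------------------------------

    def quantity(self, d: Any, where: str) -> Optional[Quantity]:
        if not isinstance(d, Mapping) or "value" not in d or "unit" not in d:
            self.err(where, "dose must be a mapping with value and unit")
            return None
        try:
            value = float(d["value"])
        except (TypeError, ValueError):
            self.err(where, f"dose value {d.get('value')!r} is not numeric")
            return None
        if value <= 0:
            self.err(where, "dose must be positive")
        per = d.get("per", "day")
        if per not in ("day", "intake"):
            self.err(where, f"dose per={per!r} must be day or intake")
        return Quantity(value=value, unit=str(d["unit"]), per=per)

    def comparator(self, op: Any, where: str, allow_in: bool = False) -> str:
        canon = _CMP_ALIASES.get(str(op))
        if canon is None or (canon == "in" and not allow_in):
            self.err(where, f"unknown operator {op!r}")
            return "="
        return canon

    def component(self, d: Any, where: str) -> Optional[ComponentPattern]:
        if d == "any":
            return ANY
        if not isinstance(d, Mapping):
            self.err(where, f"component pattern must be a mapping, got {d!r}")
            return None
        if "any" in d:
            spec = d["any"] or {}
            extra = set(d) - {"any"}
            if extra:
                self.err(where, "the Any wildcard carries no dose/form/tolerance "
                                f"constraint (found {sorted(extra)})")
            mx = spec.get("max")
            return ComponentPattern(kind="any_wildcard",
                                    min_repeat=int(spec.get("min", 0)),
                                    max_repeat=None if mx is None else int(mx))
        if "non_drug" in d:
            return ComponentPattern(kind="non_drug", non_drug=str(d["non_drug"]))
        if "class" not in d:
            self.err(where, "component pattern needs one of class/non_drug/any")
            return None
        name = str(d["class"])
        if name not in self.class_names:
            self.err(where, f"unknown drug class {name!r}")
        dose = None
        if d.get("dose") is not None:
            dd = d["dose"]
            op = self.comparator(dd.get("op", "="), f"{where}.dose")
            q = self.quantity(dd, f"{where}.dose")
            if q is not None:
                dose = DoseConstraint(op=op, quantity=q)
        tol = d.get("tolerance")
        if tol is not None and tol not in TOLERANCE_VALUES:
            self.err(where, f"tolerance {tol!r} not in {TOLERANCE_VALUES}")
        return ComponentPattern(kind="drug_class_ref", drug_class=name, dose=dose,
                                form=d.get("form"), tolerance=tol)

    def pattern(self, d: Any, where: str) -> Optional[TreatmentPattern]:
        if not isinstance(d, Mapping):
            self.err(where, f"treatment pattern must be a mapping, got {d!r}")
            return None
        comps: list[ComponentPattern] = []
        for i, cd in enumerate(d.get("components", []) or []):
            c = self.component(cd, f"{where}.components[{i}]")
            if c is not None:
                comps.append(c)
        if not comps and d.get("cardinality") is None:
            self.err(where, "pattern needs components and/or a cardinality constraint")
        status = d.get("status")
        if status is not None and status not in STATUS_VALUES:
            self.err(where, f"status {status!r} not in {STATUS_VALUES}")
        eff = d.get("efficacy")
        if eff is not None and eff not in EFFICACY_VALUES:
            self.err(where, f"efficacy {eff!r} not in {EFFICACY_VALUES}")
        overall = d.get("overall_tolerance")
        if overall is not None and overall not in TOLERANCE_VALUES:
            self.err(where, f"overall_tolerance {overall!r} not in {TOLERANCE_VALUES}")
        changes = frozenset(d.get("changes", []) or [])
        for ch in changes - set(CHANGE_KINDS):
            self.err(where, f"unknown change kind {ch!r}")
        card = d.get("cardinality")
        window = d.get("window_days")
        return TreatmentPattern(
            components=tuple(comps), status=status, efficacy=eff,
            failed=d.get("failed"), changes=changes,
            cardinality=None if card is None else int(card),
            overall_tolerance=overall,
            window_days=None if window is None else int(window))

    def condition(self, d: Any, where: str) -> Cond:
        if d is None or d is True:
            return TRUE
        if not isinstance(d, Mapping) or len(d) != 1:
            self.err(where, f"condition must be a single-key mapping, got {d!r}")
            return TRUE
        key, val = next(iter(d.items()))
        if key in ("and", "or"):
            children = [self.condition(c, f"{where}.{key}[{i}]")
                        for i, c in enumerate(val or [])]
            if len(children) < 2:
                self.err(where, f"{key.upper()} needs at least 2 sub-conditions")
            return Cond(kind=key, children=tuple(children))
        if key == "not":
            return NOT(self.condition(val, f"{where}.not"))
        if key == "clinical":
            if not isinstance(val, Sequence) or len(val) != 3:
                self.err(where, "clinical condition must be [attribute, op, value]")
                return TRUE
            attr, op, value = val
            op = self.comparator(op, where, allow_in=True)
            decl = self.attributes.get(str(attr))
            if decl is None:
                self.err(where, f"undeclared attribute {attr!r}")
            else:
                self._check_op_type(decl, op, value, where)
            if op == "in" and isinstance(value, Sequence) and not isinstance(value, str):
                value = tuple(value)
            return Cond(kind="clinical",
                        predicate=ClinicalPredicate(str(attr), op, value))
        if key == "therapeutic":
            scope = "any"
            pd = val
            if isinstance(val, Mapping) and "pattern" in val:
                scope = val.get("scope", "any")
                pd = val["pattern"]
                if scope not in ("proposed", "history", "any"):
                    self.err(where, f"unknown scope {scope!r}")
            pat = self.pattern(pd, f"{where}.therapeutic")
            return THER(pat or TreatmentPattern(cardinality=0), scope)
        if key == "native":
            if not isinstance(val, Mapping) or "name" not in val:
                self.err(where, "native condition needs a name")
                return TRUE
            params = {k: v for k, v in val.items() if k != "name"}
            return NATIVE(str(val["name"]), **params)
        self.err(where, f"unknown condition kind {key!r}")
        return TRUE

    def _check_op_type(self, decl: AttributeDecl, op: str, value: Any,
                       where: str) -> None:
        if op in ("<", "<=", ">", ">=") and decl.vtype != "number":
            self.err(where, f"ordering comparator {op!r} on non-numeric "
                            f"attribute {decl.name!r}")
        if op == "in" and (isinstance(value, str) or
                           not isinstance(value, Sequence)):
            self.err(where, "'in' needs a list of values")

    # -- templates ---------------------------------------------------------

    def template(self, d: Any, where: str) -> Optional[TreatmentTemplate]:
        if not isinstance(d, Mapping) or "name" not in d:
            self.err(where, "recommendable treatment needs a name")
            return None
        comps: list[Union[DrugSpec, NonDrug]] = []
        for i, cd in enumerate(d.get("components", []) or []):
            cw = f"{where}.components[{i}]"
            if isinstance(cd, Mapping) and "non_drug" in cd:
                comps.append(NonDrug(str(cd["non_drug"])))
            elif isinstance(cd, Mapping) and "drug" in cd:
                dd = cd["drug"]
                atc = str(dd.get("atc", ""))
                if not ATC_CODE_RE.match(atc):
                    self.err(cw, f"invalid ATC code {atc!r}")
                dose = None
                if dd.get("dose") is not None:
                    dose = self.quantity(dd["dose"], f"{cw}.dose")
                comps.append(DrugSpec(atc_code=atc, inn=str(dd.get("inn", "")),
                                      dose=dose, form=dd.get("form")))
            else:
                self.err(cw, f"template component must be drug or non_drug, got {cd!r}")
        if not comps:
            self.err(where, "recommendable treatment has no components")
            return None
        return TreatmentTemplate(name=str(d["name"]), components=tuple(comps))

    # -- recommendations ---------------------------------------------------

    def recommendation(self, d: Any, where: str) -> Optional[Recommendation]:
        if not isinstance(d, Mapping) or "id" not in d or "type" not in d:
            self.err(where, "recommendation needs id and type")
            return None
        rid, rtype = str(d["id"]), str(d["type"])
        if rtype not in REC_TYPES:
            self.err(where, f"unknown recommendation type {rtype!r}")
            return None
        cond = self.condition(d.get("conditions"), f"{where}.conditions")
        lines: list[tuple[TreatmentPattern, ...]] = []
        for i, line in enumerate(d.get("lines", []) or []):
            pats = [p for j, pd in enumerate(line or [])
                    if (p := self.pattern(pd, f"{where}.lines[{i}][{j}]")) is not None]
            if not pats:
                self.err(f"{where}.lines[{i}]", "empty treatment line")
            lines.append(tuple(pats))
        forbidden = None
        if d.get("forbidden") is not None:
            forbidden = self.pattern(d["forbidden"], f"{where}.forbidden")
        if rtype == "should_prescribe" and not lines:
            self.err(where, "should_prescribe needs at least one line (N >= 1)")
        if rtype == "should_not_prescribe" and forbidden is None:
            self.err(where, "should_not_prescribe needs a forbidden pattern")
        if rtype == "increasing_power" and len(lines) < 2:
            self.err(where, "increasing_power needs at least two power levels")
        expl = {int(k): str(v) for k, v in (d.get("explanation_labels") or {}).items()}
        adv = {int(k): str(v) for k, v in (d.get("advice_labels") or {}).items()}
        return Recommendation(
            id=rid, rec_type=rtype, conditions=cond, lines=tuple(lines),
            forbidden=forbidden, explanation_labels=expl, advice_labels=adv,
            reference_label=str(d.get("reference_label", "")),
            criticism_label=str(d.get("criticism_label", "")))

    # -- whole document ----------------------------------------------------

    def kb(self, doc: Any) -> KnowledgeBase:
        if not isinstance(doc, Mapping):
            self.err("document", "knowledge base must be a YAML mapping")
            raise KBValidationError(self.errors)
        name = str(doc.get("name", ""))
        if not name:
            self.err("name", "missing knowledge-base name")

        classes: dict[str, DrugClass] = {}
        for cname, codes in (doc.get("drug_classes") or {}).items():
            where = f"drug_classes.{cname}"
            if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", str(cname)):
                self.err(where, "class name must be an ASCII identifier")
            if not codes:
                self.err(where, "atc_codes must be non-empty")
                codes = []
            tcodes = tuple(str(c) for c in codes)
            for c in tcodes:
                if not ATC_CODE_RE.match(c):
                    self.err(where, f"invalid ATC code {c!r} (upper-case, 1-7 chars)")
            classes[str(cname)] = DrugClass(name=str(cname), atc_codes=tcodes)
        self.class_names = set(classes)
        self.non_drugs = {str(n) for n in (doc.get("non_drugs") or [])}

        for aname, ad in (doc.get("attributes") or {}).items():
            ad = ad or {}
            vtype = ad.get("type", "number")
            if vtype not in ("number", "string", "boolean"):
                self.err(f"attributes.{aname}", f"unknown value type {vtype!r}")
            grid = ad.get("grid")
            self.attributes[str(aname)] = AttributeDecl(
                name=str(aname), vtype=vtype,
                grid=None if grid is None else tuple(grid))

        templates = [t for i, td in enumerate(doc.get("recommendable_treatments") or [])
                     if (t := self.template(td, f"recommendable_treatments[{i}]"))
                     is not None]
        if not templates:
            self.err("recommendable_treatments", "recommendable treatments empty")
        tnames = [t.name for t in templates]
        if len(set(tnames)) != len(tnames):
            self.err("recommendable_treatments", "duplicate treatment names")

        recs = [r for i, rd in enumerate(doc.get("recommendations") or [])
                if (r := self.recommendation(rd, f"recommendations[{i}]")) is not None]
        if not (doc.get("recommendations") or []):
            self.err("recommendations", "recommendations empty")
        rids = [r.id for r in recs]
        if len(set(rids)) != len(rids):
            self.err("recommendations", "duplicate recommendation ids")

        gen = doc.get("generic") or {}
        applicability: dict[int, str] = {}
        for k, v in (gen.get("applicability") or {}).items():
            gid = int(k)
            if gid not in GENERIC_IDS:
                self.err("generic.applicability", f"generic id {gid} not in 1..8")
                continue
            if v not in APPLICABILITY_VALUES:
                self.err("generic.applicability",
                         f"applicability {v!r} not in {APPLICABILITY_VALUES}")
                continue
            applicability[gid] = v
        def _nameset(src: Mapping | None, label: str) -> dict[int, frozenset]:
            out: dict[int, frozenset] = {}
            for k, names in (src or {}).items():
                gid = int(k)
                if gid not in GENERIC_IDS:
                    self.err(f"generic.{label}", f"generic id {gid} not in 1..8")
                    continue
                out[gid] = frozenset(str(n) for n in (names or []))
            return out
        generic = GenericRecConfig(
            applicability=applicability,
            exceptions=_nameset(gen.get("exceptions"), "exceptions"),
            restrict_to=_nameset(gen.get("restrict_to"), "restrict_to"),
            labels={int(k): str(v) for k, v in (gen.get("labels") or {}).items()})

        ind: list[IndicationRule] = []
        for i, rd in enumerate(doc.get("indication_map") or []):
            where = f"indication_map[{i}]"
            cls = str(rd.get("class", ""))
            if cls not in classes:
                self.err(where, f"unknown drug class {cls!r}")
            ind.append(IndicationRule(
                drug_class=cls, indication=str(rd.get("indication", "")),
                dose_min=rd.get("dose_min"), dose_max=rd.get("dose_max"),
                unit=rd.get("unit")))

        kb = KnowledgeBase(
            name=name, drug_classes=classes,
            non_drugs=tuple(sorted(self.non_drugs)),
            recommendable_treatments=tuple(templates),
            recommendations=tuple(recs), generic=generic,
            indication_map=tuple(ind), attributes=dict(self.attributes))
        if self.errors:
            raise KBValidationError(self.errors)
        return kb


def load_kb(source: Union[str, Mapping, io.IOBase]) -> KnowledgeBase:
    """Load and validate a knowledge base from YAML text, a file path,
    an open stream, or an already-parsed mapping.

    Raises :class:`KBValidationError` carrying *every* schema violation
    found, each prefixed with its location in the document.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text, "r", encoding="utf-8") as fh:
                    text = fh.read()
        doc = yaml.safe_load(text)
    return _Parser().kb(doc)


def kb_from_dict(doc: Mapping) -> KnowledgeBase:
    return _Parser().kb(doc)


# --------------------------------------------------------------------------
# Serialization (load -> serialize -> load round-trips)
# --------------------------------------------------------------------------

def _quantity_to_dict(q: Quantity) -> dict:
    d: dict[str, Any] = {"value": q.value, "unit": q.unit}
    if q.per != "day":
        d["per"] = q.per
    return d


def component_to_dict(c: ComponentPattern) -> Any:
    if c.kind == "any_wildcard":
        if c.min_repeat == 0 and c.max_repeat is None:
            return "any"
        return {"any": {"min": c.min_repeat, "max": c.max_repeat}}
    if c.kind == "non_drug":
        return {"non_drug": c.non_drug}
    d: dict[str, Any] = {"class": c.drug_class}
    if c.dose is not None:
        d["dose"] = {"op": c.dose.op, **_quantity_to_dict(c.dose.quantity)}
    if c.form is not None:
        d["form"] = c.form
    if c.tolerance is not None:
        d["tolerance"] = c.tolerance
    return d


def pattern_to_dict(p: TreatmentPattern) -> dict:
    d: dict[str, Any] = {}
    if p.components:
        d["components"] = [component_to_dict(c) for c in p.components]
    for key, val in (("status", p.status), ("efficacy", p.efficacy),
                     ("failed", p.failed), ("cardinality", p.cardinality),
                     ("overall_tolerance", p.overall_tolerance),
                     ("window_days", p.window_days)):
        if val is not None:
            d[key] = val
    if p.changes:
        d["changes"] = sorted(p.changes)
    return d


def cond_to_dict(c: Cond) -> Any:
    if c.kind == "true":
        return True
    if c.kind in ("and", "or"):
        return {c.kind: [cond_to_dict(ch) for ch in c.children]}
    if c.kind == "not":
        return {"not": cond_to_dict(c.children[0])}
    if c.kind == "clinical":
        p = c.predicate
        value = list(p.value) if isinstance(p.value, tuple) else p.value
        return {"clinical": [p.attribute, p.op, value]}
    if c.kind == "therapeutic":
        return {"therapeutic": {"scope": c.scope,
                                "pattern": pattern_to_dict(c.pattern)}}
    if c.kind == "native":
        return {"native": {"name": c.native, **dict(c.params)}}
    raise ValueError(f"unknown condition kind {c.kind!r}")


def _template_to_dict(t: TreatmentTemplate) -> dict:
    comps: list[Any] = []
    for c in t.components:
        if isinstance(c, NonDrug):
            comps.append({"non_drug": c.name})
        else:
            dd: dict[str, Any] = {"atc": c.atc_code, "inn": c.inn}
            if c.dose is not None:
                dd["dose"] = _quantity_to_dict(c.dose)
            if c.form is not None:
                dd["form"] = c.form
            comps.append({"drug": dd})
    return {"name": t.name, "components": comps}


def _rec_to_dict(r: Recommendation) -> dict:
    d: dict[str, Any] = {"id": r.id, "type": r.rec_type}
    if r.conditions.kind != "true":
        d["conditions"] = cond_to_dict(r.conditions)
    if r.lines:
        d["lines"] = [[pattern_to_dict(p) for p in line] for line in r.lines]
    if r.forbidden is not None:
        d["forbidden"] = pattern_to_dict(r.forbidden)
    if r.explanation_labels:
        d["explanation_labels"] = {k: r.explanation_labels[k]
                                   for k in sorted(r.explanation_labels)}
    if r.advice_labels:
        d["advice_labels"] = {k: r.advice_labels[k] for k in sorted(r.advice_labels)}
    if r.reference_label:
        d["reference_label"] = r.reference_label
    if r.criticism_label:
        d["criticism_label"] = r.criticism_label
    return d


def kb_to_dict(kb: KnowledgeBase) -> dict:
    doc: dict[str, Any] = {
        "name": kb.name,
        "drug_classes": {n: list(c.atc_codes) for n, c in kb.drug_classes.items()},
    }
    if kb.non_drugs:
        doc["non_drugs"] = list(kb.non_drugs)
    if kb.attributes:
        doc["attributes"] = {
            n: ({"type": a.vtype} | ({"grid": list(a.grid)} if a.grid else {}))
            for n, a in kb.attributes.items()}
    doc["recommendable_treatments"] = [_template_to_dict(t)
                                       for t in kb.recommendable_treatments]
    doc["recommendations"] = [_rec_to_dict(r) for r in kb.recommendations]
    gen: dict[str, Any] = {}
    if kb.generic.applicability:
        gen["applicability"] = {k: kb.generic.applicability[k]
                                for k in sorted(kb.generic.applicability)}
    if kb.generic.exceptions:
        gen["exceptions"] = {k: sorted(v) for k, v in
                             sorted(kb.generic.exceptions.items()) if v}
    if kb.generic.restrict_to:
        gen["restrict_to"] = {k: sorted(v) for k, v in
                              sorted(kb.generic.restrict_to.items()) if v}
    if kb.generic.labels:
        gen["labels"] = {k: kb.generic.labels[k] for k in sorted(kb.generic.labels)}
    if gen:
        doc["generic"] = gen
    if kb.indication_map:
        doc["indication_map"] = [
            {"class": r.drug_class, "indication": r.indication} |
            ({"dose_min": r.dose_min} if r.dose_min is not None else {}) |
            ({"dose_max": r.dose_max} if r.dose_max is not None else {}) |
            ({"unit": r.unit} if r.unit is not None else {})
            for r in kb.indication_map]
    return doc


def kb_to_yaml(kb: KnowledgeBase) -> str:
    return yaml.safe_dump(kb_to_dict(kb), sort_keys=False, allow_unicode=True,
                          default_flow_style=False)


# --------------------------------------------------------------------------
# Cross-reference report
# --------------------------------------------------------------------------

@dataclass
class CrossRefReport:
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        if self.ok:
            return "cross-reference check: no problems found"
        return "cross-reference problems:\n" + "\n".join(
            f"  - {p}" for p in self.problems)


def _pattern_class_refs(p: TreatmentPattern) -> Iterable[str]:
    for c in p.components:
        if c.kind == "drug_class_ref" and c.drug_class:
            yield c.drug_class


def _cond_patterns(c: Cond) -> Iterable[TreatmentPattern]:
    if c.kind == "therapeutic":
        yield c.pattern
    for ch in c.children:
        yield from _cond_patterns(ch)


def validate_cross_references(kb: KnowledgeBase) -> CrossRefReport:
    """Report-only consistency check over an already-parsed KB.

    Flags dangling drug-class references, label gaps (a line reachable in a
    composed criticism without a label), and generic-recommendation
    exceptions naming entities the KB does not declare.
    """
    report = CrossRefReport()
    declared = set(kb.drug_classes)
    tnames = {t.name for t in kb.recommendable_treatments}

    def check_pattern(p: TreatmentPattern, where: str) -> None:
        for ref in _pattern_class_refs(p):
            if ref not in declared:
                report.problems.append(f"{where}: dangling drug-class reference {ref!r}")

    for r in kb.recommendations:
        for p in _cond_patterns(r.conditions):
            check_pattern(p, f"recommendation {r.id} conditions")
        for i, line in enumerate(r.lines, start=1):
            for p in line:
                check_pattern(p, f"recommendation {r.id} line {i}")
        if r.forbidden is not None:
            check_pattern(r.forbidden, f"recommendation {r.id} forbidden pattern")
        if r.rec_type == "should_prescribe":
            n = r.n_lines
            for x in range(1, n + 1):
                if not r.advice_labels.get(x):
                    report.problems.append(
                        f"recommendation {r.id}: missing advice label for line {x}")
            for y in range(2, n + 2):
                if not r.explanation_labels.get(y):
                    report.problems.append(
                        f"recommendation {r.id}: missing explanation label for line {y}")
        elif not r.criticism_label:
            report.problems.append(
                f"recommendation {r.id}: missing criticism label")

    for gid, names in kb.generic.exceptions.items():
        for n in names:
            if n not in declared and n not in tnames:
                report.problems.append(
                    f"generic #{gid} exception references undeclared entity {n!r}")
    for gid, names in kb.generic.restrict_to.items():
        for n in names:
            if n not in declared and n not in tnames:
                report.problems.append(
                    f"generic #{gid} restriction references undeclared entity {n!r}")
    for t in kb.recommendable_treatments:
        for d in t.drugs:
            if not kb.drug_class_of(d.atc_code):
                report.problems.append(
                    f"recommendable treatment {t.name}: drug {d.inn} "
                    f"({d.atc_code}) belongs to no declared class")
    return report
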