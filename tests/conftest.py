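import pytest

from rxcritic.fixtures import diabetes_kb, generic_exercise_kb, statin_kb
from rxcritic.rule_compiler import compile_kb

# The three criticism texts of the monotherapy worked example
# (explanation label + advice label; no reference label).
TEXT_STAGE1_AGI = ("AGI should be prescribed only as second-line treatment. "
                   "Guideline recommends metformin as first-line treatment.")
TEXT_STAGE1_OTHER = ("Sulfonamides, glinides and glitazones are not "
                     "recommended. Guideline recommends metformin as "
                     "first-line treatment.")
TEXT_STAGE2_OTHER = ("Sulfonamides, glinides and glitazones are not "
                     "recommended. Guideline recommends metformin as "
                     "first-line treatment, and AGI as second-line.")


@pytest.fixture(scope="session")
def dkb():
    return diabetes_kb()


@pytest.fixture(scope="session")
def dkb_rules(dkb):
    return compile_kb(dkb)


@pytest.fixture(scope="session")
def dkb_generics():
    return diabetes_kb(generics=True)


@pytest.fixture(scope="session")
def skb():
    return statin_kb()


@pytest.fixture(scope="session")
def skb_rules(skb):
    return compile_kb(skb)


@pytest.fixture(scope="session")
def skb_dataset(skb, skb_rules):
    from rxcritic.verification import build_dataset
    return build_dataset(skb, ruleset=skb_rules)


@pytest.fixture(scope="session")
def gkb():
    return generic_exercise_kb()


def simple_drug(atc, inn, dose=100, tolerance=None, unit="mg", form=None):
    d = {"atc": atc, "inn": inn, "dose": {"value": dose, "unit": unit}}
    if tolerance:
        d["tolerance"] = tolerance
    if form:
        d["form"] = form
    return {"drug": d}
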