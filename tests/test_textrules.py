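"""Phrase-rule engine: ordering, scoping, negation and level recovery."""

import pytest

import echoclean as ec
from echoclean.schema import SEVERITIES
from echoclean.synthetic import DEFAULT_PHRASE_BANK
from echoclean.textrules import (DEFAULT_RULE, PhraseRule, VariableRuleSet,
                                 classify)


@pytest.mark.parametrize("text,expected", [
    ("Systolic function appears within normal limits", "normal"),
    ("LV function appears mildly and globally impaired", "mild"),
    ("Systolic function is difficult to assess but visually appears "
     "mild-to-moderately impaired", "mild-to-moderate"),
    ("Moderate decrease in systolic function", "moderate"),
])
def test_lv_function_laboratory_phrases(rulesets, text, expected):
    assert classify(text, rulesets["lv_function"]).level == expected


@pytest.mark.parametrize("text,expected", [
    ("valve is thickened with no significant gradient", "sclerosis"),
    ("mechanical AVR in situ", "avr"),
    ("severely thickened leaflets, severe aortic stenosis", "severe"),
    ("Bioprosthetic aortic valve replacement, no stenosis", "avr"),
    ("", "none"),
])
def test_aortic_stenosis_evaluation_order(text, expected):
    assert ec.classify_aortic_stenosis(text).level == expected


@pytest.mark.parametrize("text,expected", [
    ("mild regurgitation and moderate stenosis", "mild"),
    ("There is moderate eccentric regurgitation.", "moderate"),
    ("no regurgitation seen", "none"),
    ("trivial regurgitation", "none"),
])
def test_regurgitation_direct_before_catch_all(text, expected):
    assert ec.classify_regurgitation(text, "aortic").level == expected


def test_catch_all_safety_over_severity_pairs():
    """'<s1> regurgitation ... <s2> stenosis' must grade regurgitation s1
    for every ordered pair of distinct severities."""
    for s1 in SEVERITIES:
        for s2 in SEVERITIES:
            if s1 == s2:
                continue
            text = f"{s1} regurgitation and {s2} stenosis"
            got = ec.classify_regurgitation(text, "aortic").level
            assert got == s1, (text, got)


@pytest.mark.parametrize("text,expected", [
    ("bicuspid aortic valve with raphe", "bicuspid"),
    ("", "tricuspid"),
    ("quadricuspid valve", "EXCLUDE"),
    ("normal trileaflet valve", "tricuspid"),
])
def test_av_morphology(text, expected):
    assert ec.classify_av_morphology(text).level == expected


@pytest.mark.parametrize("text,rhythm,bbb", [
    ("AF with LBBB", "atrial fibrillation", "left BBB"),
    ("sinus rhythm", "sinus rhythm", "no BBB"),
    ("paced rhythm, underlying atrial fibrillation", "artificially paced",
     "no BBB"),
    ("Atrial flutter. Right bundle branch block.", "atrial flutter",
     "right BBB"),
])
def test_rhythm_priority_and_bbb(text, rhythm, bbb):
    r, b = ec.classify_rhythm(text)
    assert (r.level, b.level) == (rhythm, bbb)


def test_la_size_prefers_text_over_volume():
    assert ec.classify_la_size("moderately dilated left atrium", 30).level == "moderate"
    assert ec.classify_la_size("", 30).level == "normal"
    assert ec.classify_la_size("", 38).level == "mild"
    assert ec.classify_la_size("", 45).level == "moderate"
    assert ec.classify_la_size("", 52).level == "severe"
    assert ec.classify_la_size("", None).level == "not stated"


def test_indication_flags_multiple_and_empty():
    flags = ec.flag_indications("murmur, query aortic stenosis")
    assert flags["murmur"] and flags["valve_assessment"]
    assert not flags["endocarditis"]
    assert not any(ec.flag_indications("").values())


def test_empty_text_returns_default_for_every_variable(rulesets):
    for name, rs in rulesets.items():
        cls = classify("", rs)
        assert cls.level == rs.default
        assert cls.matched_rule == DEFAULT_RULE


def test_phrase_bank_round_trips_to_its_level(rulesets):
    """Every template in the generator's phrase bank must classify back to
    the level it was written for — the rule sets fully cover the bank."""
    for var, levels in DEFAULT_PHRASE_BANK.items():
        if var == "indications":
            continue
        for level, phrases in levels.items():
            for phrase in phrases:
                if not phrase:
                    continue
                got = classify(phrase, rulesets[var]).level
                assert got == level, (var, phrase, got, level)


def test_classification_case_insensitive(rulesets):
    for text in ["MILD AORTIC STENOSIS.", "mild aortic stenosis."]:
        assert classify(text, rulesets["aortic_stenosis"]).level == "mild"


def test_matched_span_is_substring_of_input(rulesets):
    text = "There is MODERATE Eccentric Regurgitation near the tip."
    cls = classify(text, rulesets["aortic_regurgitation"])
    assert cls.matched_rule != DEFAULT_RULE
    assert cls.matched_span in text


def test_lower_priority_rule_insertion_does_not_shadow(rulesets):
    base = rulesets["aortic_regurgitation"]
    extra = PhraseRule(pattern="regurgitation", level="severe", priority=99,
                       kind="catch_all", scope="sentence")
    extended = VariableRuleSet(base.variable, base.levels, base.default,
                               list(base.rules) + [extra])
    for text in ["mild regurgitation", "moderate aortic regurgitation",
                 "no regurgitation"]:
        assert (classify(text, extended).level
                == classify(text, base).level)


def test_ruleset_validation_rejects_bad_definitions():
    with pytest.raises(ec.ConfigurationError):
        VariableRuleSet("x", ["a"], "b")  # default outside level set
    with pytest.raises(ec.ConfigurationError):
        VariableRuleSet("x", ["a", "b"], "a", [
            PhraseRule("p", "a", 1), PhraseRule("q", "b", 1)])  # duplicate prio
    with pytest.raises(ec.ConfigurationError):
        VariableRuleSet("x", ["a", "b"], "a", [
            PhraseRule("p", "a", 2, kind="catch_all", scope="sentence"),
            PhraseRule("q", "b", 5)])  # direct after catch-all


def test_rulesets_yaml_round_trip(tmp_path, rulesets):
    path = tmp_path / "rules.yaml"
    ec.save_rulesets(rulesets, str(path))
    loaded = ec.load_rulesets(str(path))
    assert set(loaded) == set(rulesets)
    for name in rulesets:
        assert [str(r) for r in loaded[name].rules] == \
               [str(r) for r in rulesets[name].rules]
        assert loaded[name].default == rulesets[name].default
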