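"""Numeric recoding rules: ranges, bounds, hierarchy, unit anchoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import echoclean as ec
from echoclean.numeric import (DEFAULT_NUMERIC_CONFIG, NONPOSITIVE,
                               OUT_OF_RANGE, RANGE_MEAN, UNPARSEABLE,
                               clean_heart_rate, clean_positive, compute_bmi,
                               extract_rvsp, select_lvef)


@pytest.mark.parametrize("raw,value,provenance,reason", [
    ("120–180", 150.0, RANGE_MEAN, None),      # en-dash
    ("120-180", 150.0, RANGE_MEAN, None),      # hyphen
    ("120 to 180", 150.0, RANGE_MEAN, None),
    ("72", 72.0, "direct", None),
    ("250", None, "direct", OUT_OF_RANGE),
    ("190–220", None, RANGE_MEAN, OUT_OF_RANGE),  # mean 205 > 200
    ("180–220", 200.0, RANGE_MEAN, None),         # mean exactly 200 kept
    ("garbled", None, "direct", UNPARSEABLE),
    ("", None, "direct", None),
])
def test_heart_rate_recoding(raw, value, provenance, reason):
    cv = clean_heart_rate(raw)
    if value is None:
        assert cv.is_missing
    else:
        assert cv.value == value
        assert cv.provenance == provenance
    assert cv.recode_reason == reason


@given(a=st.integers(0, 200), b=st.integers(0, 200))
@settings(max_examples=200, derandomize=True)
def test_heart_rate_range_equals_mean_of_endpoints(a, b):
    cv = clean_heart_rate(f"{a}-{b}")
    mean = (a + b) / 2
    if mean <= 200:
        assert cv.value == mean
    else:
        assert cv.is_missing and cv.recode_reason == OUT_OF_RANGE


class TestBmi:
    def test_plain_metres(self):
        bmi, flag = compute_bmi("1.8", "80")
        assert round(bmi.value, 2) == 24.69 and not flag

    def test_transposition_corrected(self):
        bmi, flag = compute_bmi("80", "1.8")
        assert flag
        assert round(bmi.value, 2) == 24.69

    def test_centimetre_height(self):
        bmi, flag = compute_bmi("180", "80")
        assert not flag
        assert round(bmi.value, 2) == 24.69

    def test_extreme_high_excluded(self):
        bmi, _ = compute_bmi("1.5", "180")  # BMI 80
        assert bmi.is_missing and bmi.recode_reason == OUT_OF_RANGE

    def test_extreme_low_excluded(self):
        bmi, _ = compute_bmi("2.0", "40")  # BMI 10
        assert bmi.is_missing and bmi.recode_reason == OUT_OF_RANGE

    def test_bounds_are_closed(self):
        # exactly 70 and exactly 14 are both excluded
        bmi, _ = compute_bmi("1.0", "70")
        assert bmi.is_missing
        bmi, _ = compute_bmi("1.0", "14")
        assert bmi.is_missing

    def test_missing_inputs(self):
        bmi, flag = compute_bmi("", "80")
        assert bmi.is_missing and bmi.recode_reason is None and not flag


@pytest.mark.parametrize("field,raw,value,reason", [
    ("ivsd", "-1.1", None, NONPOSITIVE),
    ("lvpwd", "0", None, NONPOSITIVE),
    ("aov_vmax", "3.4", 3.4, None),
    ("ivsd", "x?", None, UNPARSEABLE),
    ("ivsd", "", None, None),
])
def test_nonpositive_exclusion(field, raw, value, reason):
    cv = clean_positive(raw, field)
    if value is None:
        assert cv.is_missing
    else:
        assert cv.value == value
    assert cv.recode_reason == reason


def test_clean_positive_unknown_field_is_config_error():
    with pytest.raises(ec.ConfigurationError):
        clean_positive("1.0", "not_a_field")


def test_cleaning_is_idempotent():
    cv = clean_positive("3.4", "aov_vmax")
    again = clean_positive(str(cv.value), "aov_vmax")
    assert again.value == cv.value


class TestLvefHierarchy:
    def test_biplane_beats_teichholz(self):
        assert select_lvef({"Teichholz 2D": 55, "modified biplane": 48}).value == 48

    def test_paper_spelling_of_teichholz_accepted(self):
        assert select_lvef({"Teicholz 2D": 55}).value == 55

    def test_single_method(self):
        cv = select_lvef({"M-mode": 60})
        assert cv.value == 60 and cv.provenance == "hierarchy_selected"

    def test_empty_is_missing(self):
        assert select_lvef({}).is_missing

    def test_unknown_method_is_config_error(self):
        with pytest.raises(ec.ConfigurationError):
            select_lvef({"guesswork": 50})

    def test_insertion_of_lower_priority_method_is_invariant(self):
        base = {"modified apical four chamber": 52.0}
        extended = dict(base, **{"m-mode": 61.0, "teichholz 2d": 58.0})
        assert select_lvef(base).value == select_lvef(extended).value


@pytest.mark.parametrize("numeric,text,value,provenance", [
    ("35", "RVSP 45 mmHg", 35.0, "direct"),
    ("", "estimated RVSP of 42 mmHg plus RA pressure", 42.0, "text_extracted"),
    ("", "RVSP could not be estimated", None, None),
    ("", "gradient 30 mmHg, RVSP 44 mmHg", 44.0, "text_extracted"),  # last wins
    ("", "pressure 38mmHg", 38.0, "text_extracted"),
])
def test_rvsp_numeric_priority_and_text_anchor(numeric, text, value, provenance):
    cv = extract_rvsp(numeric, text)
    if value is None:
        assert cv.is_missing
    else:
        assert cv.value == value and cv.provenance == provenance


def test_numeric_config_validation():
    with pytest.raises(ec.ConfigurationError):
        ec.NumericRuleConfig(bmi_lower=70, bmi_upper=14)
    with pytest.raises(ec.ConfigurationError):
        ec.NumericRuleConfig(lvef_method_priority=["m-mode", "m-mode"])
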