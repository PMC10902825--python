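"""Derived variables: dimensionless index, mitral calcification flag,
diastolic-function decision tree."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoclean.derived import (DiastolicCriteria, any_mitral_calcification,
                               diastolic_function, dimensionless_index)
from echoclean.numeric import MISSING


class TestDimensionlessIndex:
    def test_ratio(self):
        assert dimensionless_index(20, 80).value == 0.25

    def test_missing_propagates(self):
        assert dimensionless_index(MISSING, 80).is_missing
        assert dimensionless_index(20, MISSING).is_missing

    @given(st.floats(0.1, 500, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_identity_ratio(self, x):
        assert dimensionless_index(x, x).value == 1.0


@pytest.mark.parametrize("mac,ms,expected", [
    ("present", "none", True),
    ("none", "none", False),
    ("not stated", "mild", True),
    ("none", "severe", True),
])
def test_any_mitral_calcification(mac, ms, expected):
    assert any_mitral_calcification(mac, ms) is expected


def _values(pos, septal_only=False):
    """Numeric inputs realising a given positivity pattern for the four
    criteria (e_over_e_prime, e_prime, tr_vmax, lavi)."""
    return dict(
        e_over_e_prime=20.0 if pos[0] else 8.0,
        e_prime_septal=5.0 if pos[1] else 9.0,
        e_prime_lateral=MISSING if septal_only else (8.0 if pos[1] else 12.0),
        tr_vmax=3.2 if pos[2] else 2.2,
        lavi=40.0 if pos[3] else 28.0,
    )


class TestDiastolicNormalEfArm:
    def test_all_negative_is_normal(self):
        res = diastolic_function(lvef=60, **_values((0, 0, 0, 0)))
        assert res.level == "normal"
        assert all(res.evaluable.values())

    def test_three_of_four_positive_is_dysfunction(self):
        assert diastolic_function(lvef=60, **_values((1, 1, 1, 0))).level \
            == "dysfunction"

    def test_exactly_half_is_indeterminate(self):
        assert diastolic_function(lvef=60, **_values((1, 1, 0, 0))).level \
            == "indeterminate"

    def test_fewer_than_two_evaluable_not_assessable(self):
        res = diastolic_function(lvef=60, tr_vmax=3.2)
        assert res.level == "not assessable"

    def test_missing_lvef_not_assessable(self):
        assert diastolic_function(lvef=MISSING, **_values((1, 1, 1, 1))).level \
            == "not assessable"

    def test_monotone_in_each_criterion(self):
        """Flipping any single criterion negative->positive never moves the
        call from dysfunction toward normal."""
        rank = {"normal": 0, "indeterminate": 1, "dysfunction": 2}
        for pos in itertools.product([0, 1], repeat=4):
            base = diastolic_function(lvef=60, **_values(pos)).level
            for i in range(4):
                if pos[i]:
                    continue
                flipped = list(pos)
                flipped[i] = 1
                after = diastolic_function(lvef=60, **_values(flipped)).level
                assert rank[after] >= rank[base], (pos, i, base, after)

    def test_missing_input_never_flips_normal_and_dysfunction(self):
        """Withholding one criterion may coarsen a call to indeterminate or
        not assessable but can never flip normal <-> dysfunction."""
        for pos in itertools.product([0, 1], repeat=4):
            vals = _values(pos)
            base = diastolic_function(lvef=60, **vals).level
            for key in ("e_over_e_prime", "tr_vmax", "lavi"):
                degraded = dict(vals, **{key: MISSING})
                after = diastolic_function(lvef=60, **degraded).level
                if base == "normal":
                    assert after != "dysfunction", (pos, key)
                if base == "dysfunction":
                    assert after != "normal", (pos, key)


class TestDiastolicReducedEfArm:
    def test_low_ea_low_e_grade_one(self):
        res = diastolic_function(lvef=40, e_over_a=0.6, mitral_e=40,
                                 **{k: v for k, v in _values((0, 0, 0, 0)).items()
                                    if k != "e_over_e_prime"})
        assert res.level == "grade I"

    def test_high_ea_grade_three(self):
        assert diastolic_function(lvef=40, e_over_a=2.5, mitral_e=90).level \
            == "grade III"

    def test_intermediate_band_resolved_by_criteria(self):
        # E/A 1.2 with E/e' and LAVi positive -> grade II
        res = diastolic_function(lvef=40, e_over_a=1.2, mitral_e=80,
                                 e_over_e_prime=18, tr_vmax=3.1, lavi=40)
        assert res.level == "grade II"
        # all three negative -> grade I
        res = diastolic_function(lvef=40, e_over_a=1.2, mitral_e=80,
                                 e_over_e_prime=8, tr_vmax=2.0, lavi=28)
        assert res.level == "grade I"

    def test_missing_inflow_not_assessable(self):
        assert diastolic_function(lvef=40).level == "not assessable"

    def test_ef_exactly_at_cutoff_uses_reduced_arm(self):
        assert diastolic_function(lvef=50, e_over_a=2.5, mitral_e=90).level \
            == "grade III"


def test_criteria_validation():
    with pytest.raises(Exception):
        DiastolicCriteria(lvef_normal_cutoff=0)
    with pytest.raises(Exception):
        DiastolicCriteria(tr_vmax_cutoff=-1)
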