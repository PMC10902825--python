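"""Variables derived from other cleaned variables.

* dimensionless index — LVOT VTI / AoV VTI, a flow-independent marker of
  aortic stenosis severity;
* any mitral calcification — annular calcification present OR any degree of
  mitral stenosis;
* diastolic function — the two-arm guideline decision tree, split on LVEF
  (normal EF defined as >50%): with normal EF, a majority vote over four
  criteria (average E/e' > 14; septal e' < 7 or lateral e' < 10 cm/s;
  TR Vmax > 2.8 m/s; LAVi > 34 mL/m2); with reduced EF, grading by mitral
  inflow (E/A and E) with the criterion vote resolving the intermediate band.

All thresholds are configuration with guideline defaults; only the >50% EF
split is fixed by the cleaning protocol itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .errors import ConfigurationError
from .numeric import MISSING, COMPUTED, CleanValue, missing

Number = Union[CleanValue, float, None]


def _val(x: Number) -> float:
    if x is None:
        return MISSING
    return float(x)


def dimensionless_index(lvot_vti: Number, aov_vti: Number) -> CleanValue:
    """Aortic valve dimensionless index: LVOT VTI divided by AoV VTI."""
    lv, ao = _val(lvot_vti), _val(aov_vti)
    if math.isnan(lv) or math.isnan(ao) or ao == 0:
        return missing(provenance=COMPUTED)
    return CleanValue(lv / ao, COMPUTED)


def any_mitral_calcification(mac_level: str, mitral_stenosis_level: str) -> bool:
    """True iff annular calcification is present or mitral stenosis is above
    'none' — the binary 'any mitral calcification' variable."""
    mac_positive = mac_level not in ("none", "not stated", "", None)
    ms_positive = mitral_stenosis_level not in ("none", "not stated", "", None)
    return bool(mac_positive or ms_positive)


@dataclass
class DiastolicCriteria:
    """Thresholds for the diastolic-function decision tree (guideline defaults).

    Units: e' cm/s, TR velocity m/s, LA volume index mL/m2, mitral E cm/s.
    """

    lvef_normal_cutoff: float = 50.0     # % — 'normal LVEF' arm is LVEF > cutoff
    e_over_e_prime_cutoff: float = 14.0  # average E/e'
    septal_e_prime_cutoff: float = 7.0   # cm/s, positive if below
    lateral_e_prime_cutoff: float = 10.0  # cm/s, positive if below
    tr_vmax_cutoff: float = 2.8          # m/s, positive if above
    lavi_cutoff: float = 34.0            # mL/m2, positive if above
    ea_low: float = 0.8                  # reduced-EF arm: E/A grade boundaries
    ea_high: float = 2.0
    e_low: float = 50.0                  # cm/s: low-E bound in the E/A<=ea_low band

    def __post_init__(self):
        for name in ("e_over_e_prime_cutoff", "septal_e_prime_cutoff",
                     "lateral_e_prime_cutoff", "tr_vmax_cutoff", "lavi_cutoff",
                     "ea_low", "ea_high", "e_low"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0 < self.lvef_normal_cutoff < 100:
            raise ConfigurationError("lvef_normal_cutoff must be in (0, 100)")


DEFAULT_DIASTOLIC_CRITERIA = DiastolicCriteria()


@dataclass(frozen=True)
class DiastolicResult:
    """Diastolic-function call plus which criteria could be evaluated."""

    level: str
    evaluable: dict
    positive: dict


def _criteria(e_over_e_prime, septal, lateral, tr_vmax, lavi,
              crit: DiastolicCriteria) -> tuple[dict, dict]:
    """Evaluability and positivity of the four guideline criteria."""
    evaluable, positive = {}, {}

    v = _val(e_over_e_prime)
    evaluable["e_over_e_prime"] = not math.isnan(v)
    positive["e_over_e_prime"] = (not math.isnan(v)) and v > crit.e_over_e_prime_cutoff

    s, l = _val(septal), _val(lateral)
    # the e' criterion is evaluable when either wall velocity is present
    evaluable["e_prime"] = not (math.isnan(s) and math.isnan(l))
    positive["e_prime"] = ((not math.isnan(s) and s < crit.septal_e_prime_cutoff)
                           or (not math.isnan(l) and l < crit.lateral_e_prime_cutoff))

    v = _val(tr_vmax)
    evaluable["tr_vmax"] = not math.isnan(v)
    positive["tr_vmax"] = (not math.isnan(v)) and v > crit.tr_vmax_cutoff

    v = _val(lavi)
    evaluable["lavi"] = not math.isnan(v)
    positive["lavi"] = (not math.isnan(v)) and v > crit.lavi_cutoff
    return evaluable, positive


def _vote(evaluable: dict, positive: dict, keys, if_majority: str,
          if_minority: str) -> str:
    n_eval = sum(evaluable[k] for k in keys)
    n_pos = sum(positive[k] for k in keys)
    if n_eval < 2:
        return "not assessable" if if_majority == "dysfunction" else "indeterminate"
    if 2 * n_pos > n_eval:
        return if_majority
    if 2 * n_pos < n_eval:
        return if_minority
    return "indeterminate"


def diastolic_function(lvef: Number = None, mitral_e: Number = None,
                       e_over_a: Number = None, e_over_e_prime: Number = None,
                       e_prime_septal: Number = None, e_prime_lateral: Number = None,
                       tr_vmax: Number = None, lavi: Number = None,
                       criteria: DiastolicCriteria = DEFAULT_DIASTOLIC_CRITERIA
                       ) -> DiastolicResult:
    """Grade diastolic function by the two-arm guideline decision tree.

    LVEF > cutoff: majority vote over the four criteria (normal /
    dysfunction / indeterminate on a tie; not assessable with fewer than two
    evaluable).  LVEF <= cutoff: grade I when E/A <= 0.8 with low E, grade III
    when E/A >= 2, otherwise the intermediate band resolved by the E/e', TR
    and LAVi criteria vote.  Missing LVEF: not assessable.
    """
    evaluable, positive = _criteria(e_over_e_prime, e_prime_septal,
                                    e_prime_lateral, tr_vmax, lavi, criteria)
    ef = _val(lvef)
    if math.isnan(ef):
        return DiastolicResult("not assessable", evaluable, positive)

    if ef > criteria.lvef_normal_cutoff:
        keys = ("e_over_e_prime", "e_prime", "tr_vmax", "lavi")
        level = _vote(evaluable, positive, keys, "dysfunction", "normal")
        return DiastolicResult(level, evaluable, positive)

    # reduced-EF arm: grade from mitral inflow
    ea = _val(e_over_a)
    if math.isnan(ea):
        return DiastolicResult("not assessable", evaluable, positive)
    e = _val(mitral_e)
    if ea <= criteria.ea_low and not math.isnan(e) and e <= criteria.e_low:
        return DiastolicResult("grade I", evaluable, positive)
    if ea >= criteria.ea_high:
        return DiastolicResult("grade III", evaluable, positive)
    # E/A <= ea_low with high/unknown E, or the intermediate E/A band:
    # resolved by the remaining criteria vote
    keys = ("e_over_e_prime", "tr_vmax", "lavi")
    level = _vote(evaluable, positive, keys, "grade II", "grade I")
    return DiastolicResult(level, evaluable, positive)
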