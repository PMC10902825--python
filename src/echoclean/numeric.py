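"""Numeric report-field recoding.

Implements the plausibility rules used to turn raw export strings into
analysable numbers: heart-rate range averaging with an upper exclusion bound,
BMI computation with extreme-value exclusion and automatic height/weight
transposition correction, the non-positive exclusion rule for measurements
that cannot be zero or less, ejection-fraction selection by method hierarchy,
and unit-anchored extraction of RVSP from free text.

Every recode is represented as a :class:`CleanValue` carrying provenance and,
when the result is missing, the reason — so an audit log can reconcile each
exclusion against the raw data.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .errors import ConfigurationError
from .schema import LVEF_METHOD_COLUMNS, NONPOSITIVE_COLUMNS

MISSING = float("nan")

# provenance values
DIRECT = "direct"
RANGE_MEAN = "range_mean"
TEXT_EXTRACTED = "text_extracted"
HIERARCHY_SELECTED = "hierarchy_selected"
COMPUTED = "computed"

# recode reasons
OUT_OF_RANGE = "out_of_range"
NONPOSITIVE = "nonpositive"
UNPARSEABLE = "unparseable"
TRANSPOSED_CORRECTED = "transposed_corrected"

LVEF_PRIORITY = list(LVEF_METHOD_COLUMNS)  # highest priority first


@dataclass(frozen=True)
class CleanValue:
    """A cleaned numeric value with provenance and recode reason."""

    value: float
    provenance: str = DIRECT
    recode_reason: Optional[str] = None

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.value)

    def __float__(self) -> float:
        return self.value


def missing(reason: Optional[str] = None, provenance: str = DIRECT) -> CleanValue:
    return CleanValue(MISSING, provenance, reason)


@dataclass
class NumericRuleConfig:
    """Bounds and field lists for numeric recoding.

    Defaults: BMI excluded at >=70 or <=14 kg/m2, heart rate excluded above
    200 bpm (strict), and the listed measurement fields recoded to missing
    when <=0.
    """

    bmi_upper: float = 70.0
    bmi_lower: float = 14.0
    hr_max: float = 200.0
    nonpositive_excluded_fields: list[str] = field(
        default_factory=lambda: list(NONPOSITIVE_COLUMNS)
        + list(LVEF_METHOD_COLUMNS.values())
    )
    lvef_method_priority: list[str] = field(default_factory=lambda: list(LVEF_PRIORITY))
    decimal_comma: bool = False

    def __post_init__(self):
        if not self.bmi_lower < self.bmi_upper:
            raise ConfigurationError("bmi_lower must be < bmi_upper")
        if self.hr_max <= 0:
            raise ConfigurationError("hr_max must be positive")
        if not self.lvef_method_priority:
            raise ConfigurationError("lvef_method_priority must be non-empty")
        if len(set(self.lvef_method_priority)) != len(self.lvef_method_priority):
            raise ConfigurationError("lvef_method_priority contains duplicates")


DEFAULT_NUMERIC_CONFIG = NumericRuleConfig()


def parse_number(raw: Optional[str], config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG
                 ) -> Optional[float]:
    """Parse a plain number from an export cell; None if empty/unparseable."""
    if raw is None:
        return None
    s = str(raw).strip()
    if not s:
        return None
    if config.decimal_comma:
        s = s.replace(",", ".")
    try:
        v = float(s)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


_NUM = r"\d+(?:\.\d+)?"
# range "a-b" with hyphen/en-dash/"to" separators (dashes already normalised
# to '-' before matching)
_RANGE_RX = re.compile(rf"^\s*({_NUM})\s*(?:-|to)\s*({_NUM})\s*$", re.IGNORECASE)
_DASHES = "‐‑‒–—"


def clean_heart_rate(raw: Optional[str],
                     config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG) -> CleanValue:
    """Recode a heart-rate cell: '120-180' becomes the range mean, 150 bpm.

    Values above ``hr_max`` (default 200 bpm, strict) are excluded.
    """
    if raw is None or not str(raw).strip():
        return missing()
    s = str(raw)
    for ch in _DASHES:
        s = s.replace(ch, "-")
    direct = parse_number(s, config)
    if direct is not None:
        if direct > config.hr_max:
            return missing(OUT_OF_RANGE)
        return CleanValue(direct, DIRECT)
    m = _RANGE_RX.match(s)
    if m:
        mean = (float(m.group(1)) + float(m.group(2))) / 2.0
        if mean > config.hr_max:
            return missing(OUT_OF_RANGE, RANGE_MEAN)
        return CleanValue(mean, RANGE_MEAN)
    return missing(UNPARSEABLE)


def clean_height_weight(height_raw: Optional[str], weight_raw: Optional[str],
                        config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG
                        ) -> tuple[Optional[float], Optional[float], bool]:
    """Parse height (m) and weight (kg), fixing transpositions and cm units.

    A pair with height in [20, 250] and weight in [1.2, 2.2] is taken to be a
    height/weight swap and corrected (flag returned True); a height above 3
    is interpreted as centimetres.
    """
    h = parse_number(height_raw, config)
    w = parse_number(weight_raw, config)
    flag = False
    if h is not None and w is not None and 20 <= h <= 250 and 1.2 <= w <= 2.2:
        h, w = w, h
        flag = True
    if h is not None and h > 3:
        h = h / 100.0
    return h, w, flag


def compute_bmi(height_raw: Optional[str], weight_raw: Optional[str],
                config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG
                ) -> tuple[CleanValue, bool]:
    """Compute BMI (kg/m2) from raw height/weight cells.

    Returns the BMI and a flag marking an automatically corrected
    height/weight transposition.  BMI >= ``bmi_upper`` or <= ``bmi_lower``
    is recoded to missing as out of plausible range.
    """
    h, w, flag = clean_height_weight(height_raw, weight_raw, config)
    if h is None or w is None:
        empty = (height_raw is None or not str(height_raw).strip()
                 or weight_raw is None or not str(weight_raw).strip())
        return missing(None if empty else UNPARSEABLE, COMPUTED), flag
    if h <= 0:
        return missing(OUT_OF_RANGE, COMPUTED), flag
    bmi = w / (h * h)
    if bmi >= config.bmi_upper or bmi <= config.bmi_lower:
        return missing(OUT_OF_RANGE, COMPUTED), flag
    return CleanValue(bmi, COMPUTED), flag


def clean_positive(raw: Optional[str], field_name: str,
                   config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG) -> CleanValue:
    """Recode a measurement that cannot be zero or less: <=0 becomes missing."""
    if field_name not in config.nonpositive_excluded_fields:
        raise ConfigurationError(
            f"{field_name!r} is not listed in nonpositive_excluded_fields"
        )
    if raw is None or not str(raw).strip():
        return missing()
    v = parse_number(raw, config)
    if v is None:
        return missing(UNPARSEABLE)
    if v <= 0:
        return missing(NONPOSITIVE)
    return CleanValue(v, DIRECT)


def _norm_method(name: str) -> str:
    s = re.sub(r"[\s_]+", " ", str(name).strip().lower())
    s = s.replace("m mode", "m-mode").replace("teicholz", "teichholz")
    return s


def select_lvef(measurements: Mapping[str, Union[CleanValue, float, None]],
                config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG) -> CleanValue:
    """Select the ejection fraction from the highest-priority method present.

    Hierarchy (first wins): modified biplane, modified apical four chamber,
    modified apical two chamber, Teichholz 2D, M-mode cube, M-mode.
    """
    normed: dict[str, float] = {}
    for name, val in measurements.items():
        key = _norm_method(name)
        if key not in config.lvef_method_priority:
            raise ConfigurationError(f"unknown LVEF method {name!r}")
        v = float(val) if val is not None else MISSING
        if not math.isnan(v):
            normed[key] = v
    for method in config.lvef_method_priority:
        if method in normed:
            return CleanValue(normed[method], HIERARCHY_SELECTED)
    return missing(provenance=HIERARCHY_SELECTED)


_RVSP_RX = re.compile(rf"({_NUM})\s*mmhg", re.IGNORECASE)


def extract_rvsp(numeric_field: Optional[str], free_text: Optional[str],
                 config: NumericRuleConfig = DEFAULT_NUMERIC_CONFIG) -> CleanValue:
    """RVSP (mmHg): prefer the numeric field, else the last number before
    'mmHg' in the free text.  Text-extracted values carry provenance
    ``text_extracted`` so they surface for audit review.
    """
    v = parse_number(numeric_field, config)
    if v is not None:
        return CleanValue(v, DIRECT)
    if free_text:
        hits = _RVSP_RX.findall(free_text)
        if hits:
            return CleanValue(float(hits[-1]), TEXT_EXTRACTED)
    return missing()
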