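"""Per-variable classification helpers built on the generic rule engine.

These wrap :func:`echoclean.textrules.classify` with the shipped rule set for
each variable and add the two pieces of non-rule logic the protocol needs:
the LA-size fallback from free text to the indexed volume, and the per-category
indication flags.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import ConfigurationError
from .schema import INDICATION_CATEGORIES
from .textrules import (Classification, VariableRuleSet, classify,
                        default_rulesets, normalize)

_VALVE_REGURG = {
    "aortic": "aortic_regurgitation",
    "mitral": "mitral_regurgitation",
    "tricuspid": "tricuspid_regurgitation",
    "pulmonary": "pulmonary_regurgitation",
}


def _rules(rulesets: Optional[Mapping[str, VariableRuleSet]], name: str
           ) -> VariableRuleSet:
    rs = default_rulesets() if rulesets is None else rulesets
    if name not in rs:
        raise ConfigurationError(f"no rule set for variable {name!r}")
    return rs[name]


def classify_aortic_stenosis(text: str, rulesets=None) -> Classification:
    """Grade calcific aortic valve disease from the aortic-valve section.

    Replacement terms win (a prosthetic valve is coded AVR regardless of other
    wording), then explicit severity, then thickened/sclerosis, then none.
    """
    return classify(text, _rules(rulesets, "aortic_stenosis"))


def classify_regurgitation(text: str, valve: str, rulesets=None) -> Classification:
    """Grade regurgitation for one valve (aortic/mitral/tricuspid/pulmonary).

    Direct wordings such as "mild regurgitation" are evaluated before the
    sentence-level severity/regurgitation co-occurrence catch-alls, so a text
    with "mild regurgitation" and "moderate stenosis" grades mild.
    """
    if valve not in _VALVE_REGURG:
        raise ConfigurationError(f"unknown valve {valve!r}")
    return classify(text, _rules(rulesets, _VALVE_REGURG[valve]))


def classify_av_morphology(text: str, rulesets=None) -> Classification:
    """Bicuspid if stated; rare morphologies marked EXCLUDE; otherwise
    tricuspid (an unremarked valve is assumed trileaflet)."""
    return classify(text, _rules(rulesets, "av_morphology"))


def classify_rhythm(text: str, rulesets=None
                    ) -> tuple[Classification, Classification]:
    """(prioritised rhythm, bundle-branch-block status) from the rhythm field."""
    return (classify(text, _rules(rulesets, "rhythm")),
            classify(text, _rules(rulesets, "bbb")))


@dataclass(frozen=True)
class LaThresholds:
    """LA volume index (mL/m2) cut-offs for guideline size grading."""

    normal_max: float = 34.0
    mild_max: float = 41.0
    moderate_max: float = 48.0


DEFAULT_LA_THRESHOLDS = LaThresholds()


def classify_la_size(text: Optional[str], lavi: Optional[float] = None,
                     thresholds: LaThresholds = DEFAULT_LA_THRESHOLDS,
                     rulesets=None) -> Classification:
    """LA size: free-text grading preferred; otherwise the indexed volume is
    binned by guideline cut-offs; otherwise not stated."""
    rs = _rules(rulesets, "la_size")
    cls = classify(text, rs)
    if cls.level != rs.default:
        return cls
    if lavi is not None and not math.isnan(float(lavi)):
        v = float(lavi)
        if v <= thresholds.normal_max:
            level = "normal"
        elif v <= thresholds.mild_max:
            level = "mild"
        elif v <= thresholds.moderate_max:
            level = "moderate"
        else:
            level = "severe"
        return Classification(level, f"lavi_threshold:{v:g}", "")
    return cls


def flag_indications(text: Optional[str],
                     categories: Optional[Mapping[str, list]] = None
                     ) -> dict[str, bool]:
    """One boolean per indication category; a study may match several."""
    if categories is None:
        categories = INDICATION_CATEGORIES
    flags = {c: False for c in categories}
    if text and text.strip():
        norm = normalize(text)
        for cat, patterns in categories.items():
            for pat in patterns:
                body = re.sub(r" +", r"\\s+", pat.strip().lower())
                if re.search(r"\b(?:%s)\b" % body, norm):
                    flags[cat] = True
                    break
    return flags
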