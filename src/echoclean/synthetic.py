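"""Synthetic echocardiography export generator with hidden ground truth.

The clinical PACS export this package cleans cannot be shared, so every
downstream stage is exercised against synthetic data that reproduces the
export's statistical structure: multi-chunk delimited files whose column
names vary by report version, free-text report sections assembled from a
laboratory phrase bank, numeric fields with ranges, unit mix-ups, impossible
values and per-field missingness, and repeat studies on the same patient.

Alongside the chunks the generator emits a :class:`GroundTruth` whose columns
hold the value a *correct* cleaning run should produce for every output
variable given the corruptions that were actually injected (an injected
non-positive wall thickness, for example, has an expected value of missing),
plus a per-corruption log whose realised counts the pipeline's audit log can
be reconciled against.

Typos never touch rule-keyword tokens by default, so label recovery measures
rule coverage, not luck; the ``adversarial`` flag additionally corrupts
keyword tokens at a configured rate for robustness testing.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import schema
from .classifiers import DEFAULT_LA_THRESHOLDS
from .derived import (DEFAULT_DIASTOLIC_CRITERIA, any_mitral_calcification,
                      diastolic_function)
from .errors import ConfigurationError
from .schema import (CLEAN_COLUMNS, DATE_COLUMN, ID_COLUMN,
                     INDICATION_CATEGORIES, LVEF_METHOD_COLUMNS, RAW_COLUMNS)
from .textrules import rule_keywords

NAN = float("nan")

# ---------------------------------------------------------------------------
# Default phrase bank: variable -> level -> report templates.  Seeded from
# phrases in common laboratory use; a local site extends these.
# ---------------------------------------------------------------------------

DEFAULT_PHRASE_BANK: dict[str, dict[str, list[str]]] = {
    "aortic_stenosis": {
        "none": ["No aortic stenosis.", "No evidence of aortic stenosis.",
                 "The aortic valve opens well."],
        "sclerosis": ["The aortic valve is thickened with no significant gradient.",
                      "Aortic valve sclerosis noted.",
                      "Mildly thickened aortic valve leaflets."],
        "mild": ["Mild aortic stenosis.", "Mild calcific aortic valve stenosis."],
        "mild-to-moderate": ["Mild-to-moderate aortic stenosis.",
                             "Mild to moderate calcific aortic stenosis."],
        "moderate": ["Moderate aortic stenosis.",
                     "Moderate calcific aortic valve stenosis."],
        "moderate-to-severe": ["Moderate-to-severe aortic stenosis.",
                               "Moderate to severe calcific aortic stenosis."],
        "severe": ["Severe aortic stenosis.",
                   "Severe calcific aortic valve stenosis.",
                   "Critical aortic stenosis."],
        "avr": ["Mechanical AVR in situ.",
                "Bioprosthetic aortic valve replacement with stable appearances.",
                "Aortic valve prosthesis seen."],
    },
    "aortic_regurgitation": {
        "none": ["No aortic regurgitation.", "Trivial aortic regurgitation."],
        "mild": ["Mild aortic regurgitation.",
                 "There is mild eccentric regurgitation.", "Mild AR."],
        "mild-to-moderate": ["Mild-to-moderate aortic regurgitation.",
                             "Mild to moderate eccentric jet of regurgitation."],
        "moderate": ["Moderate aortic regurgitation.",
                     "There is moderate eccentric regurgitation.", "Moderate AR."],
        "moderate-to-severe": ["Moderate-to-severe aortic regurgitation."],
        "severe": ["Severe aortic regurgitation.", "Severe AR."],
    },
    "av_morphology": {
        "tricuspid": ["Trileaflet aortic valve.", ""],
        "bicuspid": ["Bicuspid aortic valve.", "Bicuspid aortic valve with raphe."],
        "EXCLUDE": ["Quadricuspid aortic valve.", "Unicuspid aortic valve."],
    },
    "mitral_stenosis": {
        "none": ["No mitral stenosis."],
        "mild": ["Mild mitral stenosis.", "Mild MS."],
        "mild-to-moderate": ["Mild-to-moderate mitral stenosis."],
        "moderate": ["Moderate mitral stenosis.", "Moderate MS."],
        "moderate-to-severe": ["Moderate-to-severe mitral stenosis."],
        "severe": ["Severe mitral stenosis.", "Severe rheumatic mitral stenosis."],
    },
    "mitral_regurgitation": {
        "none": ["No mitral regurgitation.", "Trivial mitral regurgitation."],
        "mild": ["Mild mitral regurgitation.", "Mild central regurgitation.",
                 "Mild MR."],
        "mild-to-moderate": ["Mild-to-moderate mitral regurgitation."],
        "moderate": ["Moderate mitral regurgitation.", "Moderate MR.",
                     "There is moderate central regurgitation."],
        "moderate-to-severe": ["Moderate-to-severe mitral regurgitation."],
        "severe": ["Severe mitral regurgitation.", "Severe MR."],
    },
    "mitral_annular_calcification": {
        "none": ["No mitral annular calcification."],
        "present": ["Mitral annular calcification is present.",
                    "Heavily calcified mitral annulus.", "MAC noted."],
    },
    "mitral_prolapse": {
        "none": ["No prolapse seen."],
        "present": ["Mitral valve prolapse of the anterior leaflet.",
                    "The posterior leaflet prolapses."],
    },
    "tricuspid_regurgitation": {
        "none": ["No tricuspid regurgitation.", "Trivial tricuspid regurgitation."],
        "mild": ["Mild tricuspid regurgitation.", "Mild TR."],
        "mild-to-moderate": ["Mild-to-moderate tricuspid regurgitation."],
        "moderate": ["Moderate tricuspid regurgitation.", "Moderate TR."],
        "moderate-to-severe": ["Moderate-to-severe tricuspid regurgitation."],
        "severe": ["Severe tricuspid regurgitation.", "Severe TR."],
    },
    "pulmonary_stenosis": {
        "none": ["No pulmonary stenosis."],
        "mild": ["Mild pulmonary stenosis.", "Mild PS."],
        "mild-to-moderate": ["Mild-to-moderate pulmonary stenosis."],
        "moderate": ["Moderate pulmonary stenosis."],
        "moderate-to-severe": ["Moderate-to-severe pulmonary stenosis."],
        "severe": ["Severe pulmonary stenosis."],
    },
    "pulmonary_regurgitation": {
        "none": ["No pulmonary regurgitation.", "Trivial pulmonary regurgitation."],
        "mild": ["Mild pulmonary regurgitation.", "Mild PR."],
        "mild-to-moderate": ["Mild-to-moderate pulmonary regurgitation."],
        "moderate": ["Moderate pulmonary regurgitation."],
        "moderate-to-severe": ["Moderate-to-severe pulmonary regurgitation."],
        "severe": ["Severe pulmonary regurgitation."],
    },
    "lv_size": {
        "normal": ["The left ventricle is not dilated.", "Normal LV size."],
        "mild": ["Mildly dilated left ventricle.", "Mild LV dilatation."],
        "mild-to-moderate": ["Mild-to-moderately dilated left ventricle.",
                             "Mild to moderate LV dilatation."],
        "moderate": ["Moderately dilated left ventricle.", "Moderate LV dilatation."],
        "moderate-to-severe": ["Moderate-to-severely dilated left ventricle."],
        "severe": ["Severely dilated left ventricle.", "Severe LV dilatation."],
    },
    "lv_function": {
        "normal": ["Systolic function appears within normal limits.",
                   "Normal LV systolic function.", "Preserved systolic function."],
        "mild": ["LV function appears mildly and globally impaired.",
                 "Mildly impaired systolic function.", "Mild global hypokinesis."],
        "mild-to-moderate": [
            "Systolic function is difficult to assess but visually appears "
            "mild-to-moderately impaired.",
            "Mild to moderately reduced LV systolic function."],
        "moderate": ["Moderate decrease in systolic function.",
                     "Moderately impaired LV systolic function.",
                     "Moderate global hypokinesis."],
        "moderate-to-severe": ["Moderate to severely impaired systolic function.",
                               "Moderate-to-severe reduction in systolic function."],
        "severe": ["Severely impaired LV systolic function.",
                   "Severe global hypokinesis.",
                   "Severe decrease in systolic function."],
    },
    "la_size": {
        "normal": ["The left atrium is not dilated.", "Normal LA size."],
        "mild": ["Mildly dilated left atrium.", "Mild LA dilatation."],
        "mild-to-moderate": ["Mild-to-moderately dilated left atrium."],
        "moderate": ["Moderately dilated left atrium.", "Moderate LA dilatation."],
        "moderate-to-severe": ["Moderate-to-severely dilated left atrium."],
        "severe": ["Severely dilated left atrium.", "Severe LA dilatation."],
    },
    "rv_size": {
        "normal": ["The right ventricle is not dilated.", "Normal RV size."],
        "mild": ["Mildly dilated right ventricle.", "Mild RV dilatation."],
        "mild-to-moderate": ["Mild-to-moderately dilated right ventricle."],
        "moderate": ["Moderately dilated right ventricle."],
        "moderate-to-severe": ["Moderate-to-severely dilated right ventricle."],
        "severe": ["Severely dilated right ventricle."],
    },
    "rv_function": {
        "normal": ["Normal RV function.",
                   "RV systolic function appears within normal limits."],
        "mild": ["Mildly impaired RV systolic function."],
        "mild-to-moderate": ["Mild to moderately reduced RV systolic function."],
        "moderate": ["Moderately impaired RV systolic function."],
        "moderate-to-severe": ["Moderate to severely impaired RV systolic function."],
        "severe": ["Severely impaired RV systolic function."],
    },
    "rhythm": {
        "artificially paced": ["Paced rhythm.", "Ventricular pacing."],
        "supraventricular tachycardia": ["Supraventricular tachycardia.", "SVT."],
        "atrial flutter": ["Atrial flutter."],
        "atrial fibrillation": ["Atrial fibrillation.", "AF."],
        "heart block": ["Complete heart block.", "Second degree AV block."],
        "sinus rhythm": ["Sinus rhythm.", "Normal sinus rhythm.",
                         "Sinus bradycardia.", "Sinus tachycardia."],
        "other": ["Junctional rhythm.", "Frequent ectopic beats."],
        "uncertain": ["Rhythm uncertain."],
    },
    "bbb": {
        "left BBB": ["LBBB.", "Left bundle branch block."],
        "right BBB": ["RBBB.", "Right bundle branch block."],
        "BBB (unspecified)": ["Bundle branch block."],
        "no BBB": [""],
    },
    "indications": {
        "murmur": ["Systolic murmur on examination.", "Murmur heard at the apex."],
        "valve_assessment": ["Query aortic stenosis.",
                             "Assessment of valvular function.",
                             "Follow up of valve disease."],
        "heart_failure": ["Congestive heart failure.", "Assessment of LV function.",
                          "Shortness of breath."],
        "atrial_fibrillation": ["New atrial fibrillation.", "AF rate control."],
        "endocarditis": ["Query endocarditis.", "Staph bacteraemia."],
        "preoperative": ["Pre-operative assessment."],
    },
}

# prevalence of each level, emulating a general echocardiography service
DEFAULT_LEVEL_PROBS: dict[str, dict[str, float]] = {
    "aortic_stenosis": {"none": 0.45, "sclerosis": 0.18, "mild": 0.12,
                        "mild-to-moderate": 0.04, "moderate": 0.08,
                        "moderate-to-severe": 0.03, "severe": 0.06, "avr": 0.04},
    "aortic_regurgitation": {"none": 0.55, "mild": 0.22, "mild-to-moderate": 0.05,
                             "moderate": 0.10, "moderate-to-severe": 0.03,
                             "severe": 0.05},
    "av_morphology": {"tricuspid": 0.93, "bicuspid": 0.06, "EXCLUDE": 0.01},
    "mitral_stenosis": {"none": 0.85, "mild": 0.07, "mild-to-moderate": 0.02,
                        "moderate": 0.03, "moderate-to-severe": 0.01, "severe": 0.02},
    "mitral_regurgitation": {"none": 0.45, "mild": 0.28, "mild-to-moderate": 0.06,
                             "moderate": 0.12, "moderate-to-severe": 0.04,
                             "severe": 0.05},
    "mitral_annular_calcification": {"none": 0.75, "present": 0.25},
    "mitral_prolapse": {"none": 0.92, "present": 0.08},
    "tricuspid_regurgitation": {"none": 0.45, "mild": 0.30, "mild-to-moderate": 0.05,
                                "moderate": 0.12, "moderate-to-severe": 0.03,
                                "severe": 0.05},
    "pulmonary_stenosis": {"none": 0.88, "mild": 0.06, "mild-to-moderate": 0.01,
                           "moderate": 0.03, "moderate-to-severe": 0.01,
                           "severe": 0.01},
    "pulmonary_regurgitation": {"none": 0.70, "mild": 0.20, "mild-to-moderate": 0.02,
                                "moderate": 0.06, "moderate-to-severe": 0.01,
                                "severe": 0.01},
    "lv_size": {"not stated": 0.10, "normal": 0.55, "mild": 0.15,
                "mild-to-moderate": 0.04, "moderate": 0.10,
                "moderate-to-severe": 0.02, "severe": 0.04},
    "lv_function": {"not stated": 0.08, "normal": 0.55, "mild": 0.14,
                    "mild-to-moderate": 0.05, "moderate": 0.10,
                    "moderate-to-severe": 0.03, "severe": 0.05},
    "la_size": {"normal": 0.55, "mild": 0.20, "mild-to-moderate": 0.05,
                "moderate": 0.12, "moderate-to-severe": 0.03, "severe": 0.05},
    "rv_size": {"not stated": 0.12, "normal": 0.62, "mild": 0.12,
                "mild-to-moderate": 0.03, "moderate": 0.07,
                "moderate-to-severe": 0.01, "severe": 0.03},
    "rv_function": {"not stated": 0.10, "normal": 0.62, "mild": 0.12,
                    "mild-to-moderate": 0.03, "moderate": 0.08,
                    "moderate-to-severe": 0.02, "severe": 0.03},
    "rhythm": {"artificially paced": 0.05, "supraventricular tachycardia": 0.01,
               "atrial flutter": 0.03, "atrial fibrillation": 0.15,
               "heart block": 0.01, "sinus rhythm": 0.70, "other": 0.03,
               "uncertain": 0.02},
    "bbb": {"no BBB": 0.80, "left BBB": 0.08, "right BBB": 0.09,
            "BBB (unspecified)": 0.03},
}

# physiologically plausible numeric sampling ranges (units as exported)
DEFAULT_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "height": (1.40, 2.05),          # m
    "weight": (40.0, 160.0),         # kg (further constrained by plausible BMI)
    "heart_rate": (40, 180),         # bpm
    "age": (18, 95),                 # years
    "ivsd": (0.6, 1.6),              # cm
    "lvpwd": (0.6, 1.6),
    "lvot_diameter": (1.8, 2.6),
    "lvef": (20.0, 75.0),            # %
    "mitral_e": (30.0, 120.0),       # cm/s
    "mitral_a": (30.0, 110.0),
    "e_prime_septal": (4.0, 12.0),
    "e_prime_lateral": (5.0, 15.0),
    "asc_aorta_diameter": (2.5, 4.5),
    "aortic_root_diameter": (2.5, 4.5),
    "aov_vmax": (1.0, 5.0),          # m/s
    "aov_mean_gradient": (4.0, 60.0),
    "aov_vti": (15.0, 90.0),
    "lvot_vti": (10.0, 30.0),
    "aov_area": (0.6, 4.0),
    "tr_vmax": (1.5, 4.5),
    "rvsp": (15, 80),
    "lavi": (16.0, 60.0),
}

# second report version: export header -> canonical name (profile 0 is the
# canonical header itself)
DEFAULT_ALIAS_PROFILES: list[dict[str, str]] = [
    {},
    {
        "NHI": ID_COLUMN,
        "Study Date": DATE_COLUMN,
        "Pt Age": "age",
        "Pt Sex": "sex",
        "Pt Height": "height",
        "Pt Weight": "weight",
        "HR (bpm)": "heart_rate",
        "Rhythm": "rhythm_text",
        "Reason For Study": "indication_text",
        "Left Ventricle": "lv_text",
        "Left Atrium": "la_text",
        "Mitral Valve": "mitral_text",
        "Aortic Valve": "aortic_text",
        "Pulmonary Valve": "pulmonary_text",
        "Tricuspid Valve": "tricuspid_text",
        "Right Ventricle": "rv_text",
        "LVEF (Mod BP)": "lvef_modified_biplane",
        "LVEF (Mod A4C)": "lvef_modified_a4c",
        "LVEF (Mod A2C)": "lvef_modified_a2c",
        "LVEF (Teich 2D)": "lvef_teichholz_2d",
        "RVSP (mmHg)": "rvsp",
        "LAVi (mL/m2)": "lavi",
    },
]

_NONPOSITIVE_INJECTABLE = ["ivsd", "lvpwd", "lvot_diameter", "mitral_e",
                           "aov_vmax", "aov_vti", "tr_vmax"]
_MISSING_INJECTABLE = ["age", "ivsd", "lvpwd", "lvot_diameter", "mitral_a",
                       "e_prime_septal", "e_prime_lateral", "e_over_a",
                       "e_over_e_prime", "asc_aorta_diameter",
                       "aortic_root_diameter", "aov_mean_gradient", "aov_area",
                       "lvot_vti", "sex"]

_RATE_FIELDS = ["repeat_study_rate", "typo_rate", "default_missing_rate",
                "transposition_rate", "range_rate", "extreme_value_rate",
                "nonpositive_rate", "bmi_extreme_rate", "height_cm_rate",
                "adversarial_keyword_rate"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic export.

    All rates are fractions in [0, 1].  ``adversarial`` additionally corrupts
    one rule-keyword token per affected section at
    ``adversarial_keyword_rate``; by default keyword tokens are never touched.
    """

    n_studies: int = 500
    seed: int = 0
    repeat_study_rate: float = 0.10
    typo_rate: float = 0.05
    default_missing_rate: float = 0.05
    missing_rates: dict = field(default_factory=dict)
    transposition_rate: float = 0.002
    range_rate: float = 0.10
    extreme_value_rate: float = 0.005   # heart rate above the exclusion bound
    nonpositive_rate: float = 0.002     # impossible (<=0) measurement values
    bmi_extreme_rate: float = 0.002     # height/weight pairs outside BMI bounds
    height_cm_rate: float = 0.10        # height exported in centimetres
    adversarial: bool = False
    adversarial_keyword_rate: float = 0.05
    n_chunks: int = 3
    alias_profiles: list = field(
        default_factory=lambda: [dict(p) for p in DEFAULT_ALIAS_PROFILES])
    phrase_bank: dict = field(
        default_factory=lambda: {k: {l: list(v) for l, v in d.items()}
                                 for k, d in DEFAULT_PHRASE_BANK.items()})
    level_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LEVEL_PROBS.items()})
    sampling_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RANGES))

    def __post_init__(self):
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        if self.n_chunks < 1:
            raise ConfigurationError("n_chunks must be >= 1")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for r in self.missing_rates.values():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("missing_rates values must be in [0, 1]")
        for var, probs in self.level_probs.items():
            bank = self.phrase_bank.get(var, {})
            for level in probs:
                if level == "not stated" or level == "no BBB":
                    continue
                if not bank.get(level):
                    raise ConfigurationError(
                        f"phrase_bank lacks templates for {var!r} level {level!r}")

    @classmethod
    def clean(cls, n_studies: int = 100, seed: int = 0, **kw) -> "GeneratorConfig":
        """A zero-corruption configuration (round-trip testing)."""
        return cls(n_studies=n_studies, seed=seed, typo_rate=0.0,
                   default_missing_rate=0.0, transposition_rate=0.0,
                   range_rate=0.0, extreme_value_rate=0.0, nonpositive_rate=0.0,
                   bmi_extreme_rate=0.0, height_cm_rate=0.0, adversarial=False,
                   **kw)


@dataclass
class GroundTruth:
    """Expected clean output plus the realised corruption log."""

    truth: pd.DataFrame        # one row per study; expected clean values
    corruptions: pd.DataFrame  # columns: row, field, kind
    log: list[str]

    def corruption_count(self, kind: str, fld: Optional[str] = None) -> int:
        c = self.corruptions
        mask = c["kind"] == kind
        if fld is not None:
            mask &= c["field"] == fld
        return int(mask.sum())

    def gold_table(self, lookup) -> pd.DataFrame:
        """Truth keyed like the clean export (anonymous_id + study_date)."""
        out = self.truth.copy()
        out.insert(0, "anonymous_id",
                   [lookup.get(t) for t in out[ID_COLUMN]])
        return out.drop(columns=[ID_COLUMN])

    def write(self, directory) -> list[Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = [d / "ground_truth.csv", d / "corruptions.csv",
                 d / "generation_log.txt"]
        self.truth.to_csv(paths[0], index=False)
        self.corruptions.to_csv(paths[1], index=False)
        paths[2].write_text("\n".join(self.log) + "\n", encoding="utf-8")
        return paths


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _choice(rng: random.Random, probs: dict[str, float]) -> str:
    levels = list(probs)
    weights = list(probs.values())
    return rng.choices(levels, weights=weights, k=1)[0]


def _typo_word(word: str, rng: random.Random) -> str:
    """Swap two adjacent interior characters or drop one; always alters."""
    if len(word) < 3:
        return word
    if len(word) >= 4 and rng.random() < 0.5:
        i = rng.randrange(1, len(word) - 2)
        if word[i] != word[i + 1]:
            return word[:i] + word[i + 1] + word[i] + word[i + 2:]
    i = rng.randrange(1, len(word) - 1)
    return word[:i] + word[i + 1:]


def _apply_typos(text: str, rng: random.Random, rate: float,
                 protected: set[str]) -> str:
    if not text or rate <= 0:
        return text
    out = []
    for tok in text.split(" "):
        core = tok.strip(string.punctuation)
        if (len(core) >= 4 and core.isalpha()
                and core.lower() not in protected and rng.random() < rate):
            tok = tok.replace(core, _typo_word(core, rng), 1)
        out.append(tok)
    return " ".join(out)


def _corrupt_keyword(text: str, rng: random.Random, protected: set[str]) -> str:
    """Corrupt one keyword-token occurrence; returns text unchanged if none."""
    toks = text.split(" ")
    idxs = [i for i, t in enumerate(toks)
            if len(t.strip(string.punctuation)) >= 3
            and t.strip(string.punctuation).lower() in protected]
    if not idxs:
        return text
    i = rng.choice(idxs)
    core = toks[i].strip(string.punctuation)
    toks[i] = toks[i].replace(core, _typo_word(core, rng), 1)
    return " ".join(toks)


def _fmt(v: float, nd: int = 2) -> str:
    r = round(float(v), nd)
    if r == int(r):
        return str(int(r))
    return str(r)


class _StudyFactory:
    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = random.Random(config.seed)
        self.protected = rule_keywords() | {"mmhg"}
        for pats in INDICATION_CATEGORIES.values():
            for p in pats:
                for w in p.replace("|", " ").split():
                    self.protected.add(w.lower())
        self.corruptions: list[tuple[int, str, str]] = []
        self.log: list[str] = []
        self._row = 0

    # -- helpers ------------------------------------------------------------
    def _rate(self, fld: str) -> float:
        return self.cfg.missing_rates.get(fld, self.cfg.default_missing_rate)

    def _corrupt(self, fld: str, kind: str):
        self.corruptions.append((self._row, fld, kind))
        self.log.append(f"row={self._row} field={fld} corruption={kind}")

    def _phrase(self, var: str, level: str) -> str:
        return self.rng.choice(self.cfg.phrase_bank[var][level])

    def _sample(self, fld: str, nd: int = 2) -> float:
        lo, hi = self.cfg.sampling_ranges[fld]
        return round(self.rng.uniform(lo, hi), nd)

    def _finish_text(self, text: str, section: str) -> str:
        rng, cfg = self.rng, self.cfg
        text = _apply_typos(text, rng, cfg.typo_rate, self.protected)
        if cfg.adversarial and text and rng.random() < cfg.adversarial_keyword_rate:
            new = _corrupt_keyword(text, rng, self.protected)
            if new != text:
                self._corrupt(section, "keyword_typo")
            text = new
        return text

    # -- one study ----------------------------------------------------------
    def study(self, row: int, patient_id: str, date: dt.date) -> tuple[dict, dict]:
        self._row = row
        rng, cfg = self.rng, self.cfg
        raw: dict[str, str] = {c: "" for c in RAW_COLUMNS}
        truth: dict[str, object] = {c: NAN for c in CLEAN_COLUMNS}
        raw[ID_COLUMN] = patient_id
        raw[DATE_COLUMN] = date.isoformat()
        truth[ID_COLUMN] = patient_id
        truth[DATE_COLUMN] = date.isoformat()

        # demographics -------------------------------------------------------
        age = rng.randint(*map(int, cfg.sampling_ranges["age"]))
        if rng.random() < self._rate("age"):
            raw["age"] = ""
            self._corrupt("age", "missing")
        else:
            raw["age"] = str(age)
            truth["age"] = float(age)
        sex = rng.choice(["female", "male"])
        sex_raw = rng.choice({"female": ["F", "Female"], "male": ["M", "Male"]}[sex])
        if rng.random() < self._rate("sex"):
            raw["sex"] = ""
            truth["sex"] = ""
            self._corrupt("sex", "missing")
        else:
            raw["sex"] = sex_raw
            truth["sex"] = sex

        # height / weight / BMI ---------------------------------------------
        h = self._sample("height")
        wlo, whi = cfg.sampling_ranges["weight"]
        # constrain weight so the plausible-range BMI bounds cannot fire
        lo = max(wlo, 15.5 * h * h)
        hi = min(whi, 65.0 * h * h)
        w = round(rng.uniform(lo, hi), 1)
        u = rng.random()
        if u < cfg.transposition_rate:
            raw["height"], raw["weight"] = _fmt(w, 1), _fmt(h, 2)
            truth["height"], truth["weight"] = h, w
            truth["bmi"] = w / (h * h)
            self._corrupt("height", "transposed")
        elif u < cfg.transposition_rate + cfg.bmi_extreme_rate:
            if rng.random() < 0.5:
                w = round(72.0 * h * h + rng.uniform(0.0, 30.0), 1)
            else:
                w = round(12.0 * h * h - rng.uniform(0.0, 3.0), 1)
            raw["height"], raw["weight"] = _fmt(h, 2), _fmt(w, 1)
            truth["height"], truth["weight"] = h, w
            truth["bmi"] = NAN
            self._corrupt("bmi", "bmi_extreme")
        else:
            hm = rng.random() < self._rate("height")
            wm = rng.random() < self._rate("weight")
            if rng.random() < cfg.height_cm_rate:
                raw["height"] = str(int(round(h * 100)))
            else:
                raw["height"] = _fmt(h, 2)
            raw["weight"] = _fmt(w, 1)
            truth["height"], truth["weight"] = h, w
            truth["bmi"] = w / (h * h)
            if hm:
                raw["height"] = ""
                truth["height"] = NAN
                truth["bmi"] = NAN
                self._corrupt("height", "missing")
            if wm:
                raw["weight"] = ""
                truth["weight"] = NAN
                truth["bmi"] = NAN
                self._corrupt("weight", "missing")

        # heart rate ---------------------------------------------------------
        hr = rng.randint(*map(int, cfg.sampling_ranges["heart_rate"]))
        u = rng.random()
        if u < cfg.extreme_value_rate:
            raw["heart_rate"] = str(rng.randint(205, 250))
            truth["heart_rate"] = NAN
            self._corrupt("heart_rate", "hr_out_of_range")
        elif u < cfg.extreme_value_rate + cfg.range_rate:
            d = rng.choice([5, 10, 15, 20])
            raw["heart_rate"] = f"{hr - d}–{hr + d}"
            truth["heart_rate"] = float(hr)
            self._corrupt("heart_rate", "range_formatted")
        elif rng.random() < self._rate("heart_rate"):
            raw["heart_rate"] = ""
            truth["heart_rate"] = NAN
            self._corrupt("heart_rate", "missing")
        else:
            raw["heart_rate"] = str(hr)
            truth["heart_rate"] = float(hr)

        # rhythm and bundle branch block --------------------------------------
        rhythm = _choice(rng, cfg.level_probs["rhythm"])
        bbb = _choice(rng, cfg.level_probs["bbb"])
        parts = [self._phrase("rhythm", rhythm)]
        if bbb != "no BBB":
            parts.append(self._phrase("bbb", bbb))
        raw["rhythm_text"] = self._finish_text(" ".join(p for p in parts if p),
                                               "rhythm_text")
        truth["rhythm"], truth["bbb"] = rhythm, bbb

        # indications ----------------------------------------------------------
        k = rng.choices([0, 1, 2, 3], weights=[0.10, 0.50, 0.30, 0.10], k=1)[0]
        cats = rng.sample(list(INDICATION_CATEGORIES), k)
        raw["indication_text"] = self._finish_text(
            " ".join(self._phrase("indications", c) for c in cats),
            "indication_text")
        for c in INDICATION_CATEGORIES:
            truth[f"indication_{c}"] = c in cats

        # plain numeric measurements ------------------------------------------
        for fld in ["ivsd", "lvpwd", "lvot_diameter", "mitral_a",
                    "e_prime_septal", "e_prime_lateral", "asc_aorta_diameter",
                    "aortic_root_diameter", "aov_mean_gradient", "aov_area",
                    "lvot_vti", "aov_vti", "mitral_e", "aov_vmax", "tr_vmax"]:
            v = self._sample(fld)
            u = rng.random()
            if fld in _NONPOSITIVE_INJECTABLE and u < cfg.nonpositive_rate:
                bad = 0.0 if rng.random() < 0.3 else round(rng.uniform(-9.9, -0.1), 2)
                raw[fld] = _fmt(bad, 2)
                truth[fld] = NAN
                self._corrupt(fld, "nonpositive")
            elif fld in _MISSING_INJECTABLE and rng.random() < self._rate(fld):
                raw[fld] = ""
                truth[fld] = NAN
                self._corrupt(fld, "missing")
            else:
                raw[fld] = _fmt(v, 2)
                truth[fld] = round(v, 2)

        # derived ratios written by the reporting software
        if not math.isnan(truth["mitral_e"]) and not math.isnan(truth["mitral_a"]):
            ea = round(truth["mitral_e"] / truth["mitral_a"], 2)
        else:
            ea = round(rng.uniform(0.5, 2.5), 2)
        es, el = truth["e_prime_septal"], truth["e_prime_lateral"]
        if not math.isnan(truth["mitral_e"]) and not (math.isnan(es) or math.isnan(el)):
            ee = round(truth["mitral_e"] / ((es + el) / 2.0), 1)
        else:
            ee = round(rng.uniform(4.0, 20.0), 1)
        for fld, v in [("e_over_a", ea), ("e_over_e_prime", ee)]:
            if rng.random() < self._rate(fld):
                raw[fld] = ""
                truth[fld] = NAN
                self._corrupt(fld, "missing")
            else:
                raw[fld] = _fmt(v, 2)
                truth[fld] = round(v, 2)

        # dimensionless index (derived downstream, never exported raw)
        if not math.isnan(truth["lvot_vti"]) and not math.isnan(truth["aov_vti"]):
            truth["dimensionless_index"] = truth["lvot_vti"] / truth["aov_vti"]

        # LVEF method hierarchy -------------------------------------------------
        lvef = self._sample("lvef", 1)
        present = []
        for method, col in LVEF_METHOD_COLUMNS.items():
            p = {"modified biplane": 0.50, "modified apical four chamber": 0.20,
                 "modified apical two chamber": 0.10, "teichholz 2d": 0.30,
                 "m-mode cube": 0.10, "m-mode": 0.20}[method]
            if rng.random() < p:
                v = round(max(10.0, lvef + rng.uniform(-5.0, 5.0)), 1)
                raw[col] = _fmt(v, 1)
                present.append((method, v))
        truth["lvef"] = present[0][1] if present else NAN

        # LV / LA / RV free text -------------------------------------------------
        lv_size = _choice(rng, cfg.level_probs["lv_size"])
        lv_function = _choice(rng, cfg.level_probs["lv_function"])
        parts = []
        if lv_size != "not stated":
            parts.append(self._phrase("lv_size", lv_size))
        if lv_function != "not stated":
            parts.append(self._phrase("lv_function", lv_function))
        raw["lv_text"] = self._finish_text(" ".join(parts), "lv_text")
        truth["lv_size"], truth["lv_function"] = lv_size, lv_function

        rv_size = _choice(rng, cfg.level_probs["rv_size"])
        rv_function = _choice(rng, cfg.level_probs["rv_function"])
        parts = []
        if rv_size != "not stated":
            parts.append(self._phrase("rv_size", rv_size))
        if rv_function != "not stated":
            parts.append(self._phrase("rv_function", rv_function))
        raw["rv_text"] = self._finish_text(" ".join(parts), "rv_text")
        truth["rv_size"], truth["rv_function"] = rv_size, rv_function

        # LA: free text preferred, LAVi fallback
        lavi = self._sample("lavi", 1)
        lavi_present = rng.random() < 0.80
        text_present = rng.random() < 0.85
        if text_present:
            la = _choice(rng, cfg.level_probs["la_size"])
            raw["la_text"] = self._finish_text(self._phrase("la_size", la), "la_text")
        elif lavi_present:
            t = DEFAULT_LA_THRESHOLDS
            la = ("normal" if lavi <= t.normal_max else
                  "mild" if lavi <= t.mild_max else
                  "moderate" if lavi <= t.moderate_max else "severe")
        else:
            la = "not stated"
        if lavi_present:
            raw["lavi"] = _fmt(lavi, 1)
            truth["lavi"] = round(lavi, 1)
        truth["la_size"] = la

        # valve sections ---------------------------------------------------------
        def level_of(var):
            return _choice(rng, cfg.level_probs[var])

        def maybe_phrase(var, level, explicit_default_p=0.30):
            """Default levels are stated explicitly only some of the time."""
            defaults = {"av_morphology": "tricuspid"}
            default = defaults.get(var, "none")
            if level == default and rng.random() >= explicit_default_p:
                return ""
            return self._phrase(var, level)

        a_sten = level_of("aortic_stenosis")
        a_reg = level_of("aortic_regurgitation")
        morph = level_of("av_morphology")
        parts = [self._phrase("aortic_stenosis", a_sten)
                 if a_sten != "none" else maybe_phrase("aortic_stenosis", a_sten),
                 self._phrase("aortic_regurgitation", a_reg)
                 if a_reg != "none" else maybe_phrase("aortic_regurgitation", a_reg),
                 self._phrase("av_morphology", morph)
                 if morph != "tricuspid" else maybe_phrase("av_morphology", morph)]
        raw["aortic_text"] = self._finish_text(
            " ".join(p for p in parts if p), "aortic_text")
        truth["aortic_stenosis"] = a_sten
        truth["aortic_regurgitation"] = a_reg
        truth["av_morphology"] = morph

        m_sten = level_of("mitral_stenosis")
        m_reg = level_of("mitral_regurgitation")
        mac = level_of("mitral_annular_calcification")
        prol = level_of("mitral_prolapse")
        parts = [maybe_phrase("mitral_stenosis", m_sten)
                 if m_sten == "none" else self._phrase("mitral_stenosis", m_sten),
                 maybe_phrase("mitral_regurgitation", m_reg)
                 if m_reg == "none" else self._phrase("mitral_regurgitation", m_reg),
                 maybe_phrase("mitral_annular_calcification", mac, 0.15)
                 if mac == "none"
                 else self._phrase("mitral_annular_calcification", mac),
                 maybe_phrase("mitral_prolapse", prol, 0.10)
                 if prol == "none" else self._phrase("mitral_prolapse", prol)]
        raw["mitral_text"] = self._finish_text(
            " ".join(p for p in parts if p), "mitral_text")
        truth["mitral_stenosis"] = m_sten
        truth["mitral_regurgitation"] = m_reg
        truth["mitral_annular_calcification"] = mac
        truth["mitral_prolapse"] = prol
        truth["any_mitral_calcification"] = any_mitral_calcification(mac, m_sten)

        p_sten = level_of("pulmonary_stenosis")
        p_reg = level_of("pulmonary_regurgitation")
        parts = [maybe_phrase("pulmonary_stenosis", p_sten)
                 if p_sten == "none" else self._phrase("pulmonary_stenosis", p_sten),
                 maybe_phrase("pulmonary_regurgitation", p_reg)
                 if p_reg == "none"
                 else self._phrase("pulmonary_regurgitation", p_reg)]
        raw["pulmonary_text"] = self._finish_text(
            " ".join(p for p in parts if p), "pulmonary_text")
        truth["pulmonary_stenosis"] = p_sten
        truth["pulmonary_regurgitation"] = p_reg

        t_reg = level_of("tricuspid_regurgitation")
        parts = [maybe_phrase("tricuspid_regurgitation", t_reg)
                 if t_reg == "none"
                 else self._phrase("tricuspid_regurgitation", t_reg)]
        # RVSP: numeric field preferred, else stated in the tricuspid text
        rvsp = rng.randint(*map(int, cfg.sampling_ranges["rvsp"]))
        mode = rng.random()
        if mode < 0.50:
            raw["rvsp"] = str(rvsp)
            truth["rvsp"] = float(rvsp)
        elif mode < 0.80:
            parts.append(f"Estimated RVSP {rvsp} mmHg.")
            truth["rvsp"] = float(rvsp)
        raw["tricuspid_text"] = self._finish_text(
            " ".join(p for p in parts if p), "tricuspid_text")
        truth["tricuspid_regurgitation"] = t_reg

        # diastolic function from the expected cleaned measurements
        truth["diastolic_function"] = diastolic_function(
            lvef=truth["lvef"], mitral_e=truth["mitral_e"],
            e_over_a=truth["e_over_a"], e_over_e_prime=truth["e_over_e_prime"],
            e_prime_septal=truth["e_prime_septal"],
            e_prime_lateral=truth["e_prime_lateral"],
            tr_vmax=truth["tr_vmax"], lavi=truth["lavi"],
            criteria=DEFAULT_DIASTOLIC_CRITERIA).level
        return raw, truth


def _nhi(rng: random.Random, used: set[str]) -> str:
    letters = "ABCDEFGHJKLMNPQRSTUVWXYZ"
    while True:
        nhi = ("".join(rng.choice(letters) for _ in range(3))
               + "".join(rng.choice(string.digits) for _ in range(4)))
        if nhi not in used:
            used.add(nhi)
            return nhi


def generate_export(config: GeneratorConfig
                    ) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Generate the raw export chunks and their ground truth.

    Deterministic given the config (including seed): identical inputs yield
    byte-identical chunks and ground truth.
    """
    factory = _StudyFactory(config)
    rng = factory.rng
    used: set[str] = set()
    base = dt.date(2010, 1, 1)
    span = (dt.date(2018, 12, 31) - base).days

    # patients and study dates; repeat studies get strictly later dates
    studies: list[tuple[str, dt.date]] = []
    while len(studies) < config.n_studies:
        pid = _nhi(rng, used)
        d0 = base + dt.timedelta(days=rng.randrange(span + 1))
        studies.append((pid, d0))
        if rng.random() < config.repeat_study_rate and len(studies) < config.n_studies:
            studies.append((pid, d0 + dt.timedelta(days=rng.randrange(30, 1001))))

    raws, truths = [], []
    for row, (pid, date) in enumerate(studies):
        raw, truth = factory.study(row, pid, date)
        raws.append(raw)
        truths.append(truth)
    raw_df = pd.DataFrame(raws, columns=RAW_COLUMNS, dtype=str).fillna("")
    truth_cols = [ID_COLUMN if c == "anonymous_id" else c for c in CLEAN_COLUMNS]
    truth_df = pd.DataFrame(truths)[truth_cols]
    corruptions = pd.DataFrame(factory.corruptions or None,
                               columns=["row", "field", "kind"])
    gt = GroundTruth(truth_df, corruptions, factory.log)

    # split into chunks; each chunk is written under one alias profile
    chunks = []
    bounds = np.linspace(0, len(raw_df), config.n_chunks + 1).astype(int)
    for i in range(config.n_chunks):
        chunk = raw_df.iloc[bounds[i]:bounds[i + 1]].reset_index(drop=True)
        profile = config.alias_profiles[i % len(config.alias_profiles)]
        inverse = {canon: alias for alias, canon in profile.items()}
        chunk = chunk.rename(columns=inverse)
        chunks.append(chunk)
    gt.log.append(f"generated {len(raw_df)} studies over {len(used)} patients "
                  f"in {config.n_chunks} chunks")
    return chunks, gt


def write_chunks(chunks: list[pd.DataFrame], directory,
                 prefix: str = "export_chunk") -> list[Path]:
    """Write one UTF-8 CSV (quoted fields, header row) per chunk."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, chunk in enumerate(chunks):
        p = d / f"{prefix}_{i:03d}.csv"
        chunk.to_csv(p, index=False, quoting=csv.QUOTE_ALL,
                     lineterminator="\n", encoding="utf-8")
        paths.append(p)
    return paths
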