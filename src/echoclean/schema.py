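"""Canonical column names and categorical level sets.

Echocardiography exports name the same quantity differently between report
versions; the pipeline maps every export header onto the canonical names
below before any cleaning happens.  Categorical variables use an ordinal
severity lattice (none < sclerosis < mild < mild-to-moderate < moderate <
moderate-to-severe < severe) plus variable-specific extra levels such as a
replaced valve (AVR).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Canonical raw (input) columns
# ---------------------------------------------------------------------------

ID_COLUMN = "patient_id"
DATE_COLUMN = "study_date"

TEXT_COLUMNS = [
    "indication_text",
    "rhythm_text",
    "lv_text",
    "la_text",
    "mitral_text",
    "aortic_text",
    "pulmonary_text",
    "tricuspid_text",
    "rv_text",
]

LVEF_METHOD_COLUMNS = {
    "modified biplane": "lvef_modified_biplane",
    "modified apical four chamber": "lvef_modified_a4c",
    "modified apical two chamber": "lvef_modified_a2c",
    "teichholz 2d": "lvef_teichholz_2d",
    "m-mode cube": "lvef_mmode_cube",
    "m-mode": "lvef_mmode",
}

# numeric columns cleaned with the non-positive exclusion rule
NONPOSITIVE_COLUMNS = [
    "ivsd",
    "lvpwd",
    "lvot_diameter",
    "mitral_e",
    "mitral_a",
    "e_prime_septal",
    "e_prime_lateral",
    "e_over_a",
    "e_over_e_prime",
    "asc_aorta_diameter",
    "aortic_root_diameter",
    "aov_vmax",
    "aov_mean_gradient",
    "aov_vti",
    "lvot_vti",
    "aov_area",
    "tr_vmax",
]

OTHER_NUMERIC_COLUMNS = ["age", "height", "weight", "heart_rate", "lavi", "rvsp"]

RAW_COLUMNS = (
    [ID_COLUMN, DATE_COLUMN, "age", "sex", "height", "weight", "heart_rate"]
    + TEXT_COLUMNS
    + ["lavi"]
    + NONPOSITIVE_COLUMNS
    + list(LVEF_METHOD_COLUMNS.values())
    + ["rvsp"]
)

# ---------------------------------------------------------------------------
# Categorical level sets
# ---------------------------------------------------------------------------

EXCLUDE = "EXCLUDE"  # marker level: record dropped from analyses of that variable

SEVERITIES = ["mild", "mild-to-moderate", "moderate", "moderate-to-severe", "severe"]
VALVE_LEVELS = ["none"] + SEVERITIES
AS_LEVELS = ["none", "sclerosis"] + SEVERITIES + ["avr"]
GRADED_LEVELS = ["not stated", "normal"] + SEVERITIES  # size / function grading

RHYTHM_LEVELS = [
    "artificially paced",
    "supraventricular tachycardia",
    "atrial flutter",
    "atrial fibrillation",
    "heart block",
    "sinus rhythm",
    "other",
    "uncertain",
]
BBB_LEVELS = ["no BBB", "left BBB", "right BBB", "BBB (unspecified)"]

DIASTOLIC_LEVELS = [
    "normal",
    "dysfunction",
    "grade I",
    "grade II",
    "grade III",
    "indeterminate",
    "not assessable",
]

# variables produced by free-text classification
CATEGORICAL_VARIABLES = {
    "aortic_stenosis": AS_LEVELS,
    "aortic_regurgitation": VALVE_LEVELS,
    "av_morphology": ["tricuspid", "bicuspid", EXCLUDE],
    "mitral_stenosis": VALVE_LEVELS,
    "mitral_regurgitation": VALVE_LEVELS,
    "mitral_annular_calcification": ["none", "present"],
    "mitral_prolapse": ["none", "present"],
    "tricuspid_regurgitation": VALVE_LEVELS,
    "pulmonary_stenosis": VALVE_LEVELS,
    "pulmonary_regurgitation": VALVE_LEVELS,
    "lv_size": GRADED_LEVELS,
    "lv_function": GRADED_LEVELS,
    "la_size": GRADED_LEVELS,
    "rv_size": GRADED_LEVELS,
    "rv_function": GRADED_LEVELS,
    "rhythm": RHYTHM_LEVELS,
    "bbb": BBB_LEVELS,
}

# default indication categories (a local laboratory would extend these)
INDICATION_CATEGORIES = {
    "murmur": ["murmur"],
    "valve_assessment": [
        "valve", "valvular", "stenosis", "regurgitation", "aortic stenosis",
    ],
    "heart_failure": [
        "heart failure", "chf", "cardiomyopathy", "dyspnoea|dyspnea",
        "shortness of breath", "lv function",
    ],
    "atrial_fibrillation": ["atrial fibrillation", "af"],
    "endocarditis": ["endocarditis", "vegetation", "bacteraemia|bacteremia"],
    "preoperative": ["pre op|preoperative|pre operative", "surgical workup"],
}

INDICATION_FLAG_COLUMNS = [f"indication_{c}" for c in INDICATION_CATEGORIES]

# optional map collapsing intermediate grades onto four-grade analyses
COLLAPSE_INTERMEDIATE = {
    "mild-to-moderate": "moderate",
    "moderate-to-severe": "severe",
}

# ---------------------------------------------------------------------------
# Clean (output) record columns, in export order
# ---------------------------------------------------------------------------

CLEAN_COLUMNS = (
    ["anonymous_id", DATE_COLUMN, "age", "sex", "height", "weight", "bmi",
     "heart_rate", "rhythm", "bbb"]
    + INDICATION_FLAG_COLUMNS
    + ["ivsd", "lvpwd", "lvot_diameter", "lvef",
       "lv_size", "lv_function", "la_size", "lavi",
       "mitral_e", "mitral_a", "e_prime_septal", "e_prime_lateral",
       "e_over_a", "e_over_e_prime",
       "mitral_stenosis", "mitral_regurgitation",
       "mitral_annular_calcification", "mitral_prolapse",
       "any_mitral_calcification",
       "asc_aorta_diameter", "aortic_root_diameter", "aov_vmax",
       "aov_mean_gradient", "aov_vti", "lvot_vti", "aov_area",
       "dimensionless_index",
       "aortic_stenosis", "aortic_regurgitation", "av_morphology",
       "pulmonary_stenosis", "pulmonary_regurgitation",
       "tricuspid_regurgitation", "tr_vmax", "rvsp",
       "diastolic_function", "rv_size", "rv_function"]
)
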