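"""End-to-end cleaning pipeline.

Stage order: load and stitch the export chunks, resolve column aliases,
anonymise patient identifiers, drop all-missing columns, then clean in
sequence — demographics and BMI, indications, rhythm and heart rate, left
ventricular numerics, LV/LA free text, mitral valve, aortic valve, pulmonary
valve, tricuspid valve, RVSP, diastolic function, right ventricle — and
finally export only the typed clean record (no raw free text), collapsed to
the earliest study per patient unless ``keep_all`` is requested.

Every recode, classification fallback and exclusion is written to an audit
log so realised corruption counts can be reconciled row by row.
"""

from __future__ import annotations

import glob as globmod
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import numeric as num
from .classifiers import (DEFAULT_LA_THRESHOLDS, LaThresholds,
                          classify_aortic_stenosis, classify_av_morphology,
                          classify_la_size, classify_regurgitation,
                          classify_rhythm, flag_indications)
from .deidentify import LookupTable, anonymize, write_lookup
from .derived import (DEFAULT_DIASTOLIC_CRITERIA, DiastolicCriteria,
                      any_mitral_calcification, diastolic_function,
                      dimensionless_index)
from .errors import ConfigurationError
from .schema import (CLEAN_COLUMNS, DATE_COLUMN, ID_COLUMN,
                     INDICATION_CATEGORIES, LVEF_METHOD_COLUMNS, RAW_COLUMNS,
                     TEXT_COLUMNS)
from .synthetic import DEFAULT_ALIAS_PROFILES
from .textrules import DEFAULT_RULE, classify, load_rulesets

MANDATORY_COLUMNS = [ID_COLUMN, DATE_COLUMN]

_SEX_MAP = {"f": "female", "female": "female", "m": "male", "male": "male"}


@dataclass(frozen=True)
class AuditEntry:
    row: object
    field: str
    raw: str
    action: str
    reason: Optional[str] = None

    def line(self) -> str:
        return (f"row={self.row} field={self.field} raw={self.raw!r} "
                f"action={self.action} reason={self.reason or '-'}")


class AuditLog:
    """Line-oriented record of every recode/flag the pipeline performs."""

    def __init__(self):
        self.entries: list[AuditEntry] = []

    def add(self, row, field, raw, action, reason=None):
        self.entries.append(AuditEntry(row, str(field), str(raw), action, reason))

    def count(self, field: Optional[str] = None, action: Optional[str] = None,
              reason: Optional[str] = None) -> int:
        return sum(1 for e in self.entries
                   if (field is None or e.field == field)
                   and (action is None or e.action == action)
                   and (reason is None or e.reason == reason))

    def lines(self) -> list[str]:
        return [e.line() for e in self.entries]

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.lines()) + "\n", encoding="utf-8")


@dataclass
class PipelineConfig:
    """Everything the `run` orchestrator needs."""

    inputs: Sequence = ()                 # paths, globs, or DataFrames
    alias_profiles: list = dc_field(
        default_factory=lambda: [dict(p) for p in DEFAULT_ALIAS_PROFILES])
    numeric: num.NumericRuleConfig = dc_field(default_factory=num.NumericRuleConfig)
    rules_path: Optional[str] = None      # None -> shipped defaults
    la_thresholds: LaThresholds = DEFAULT_LA_THRESHOLDS
    diastolic: DiastolicCriteria = dc_field(
        default_factory=lambda: DEFAULT_DIASTOLIC_CRITERIA)
    indication_categories: dict = dc_field(
        default_factory=lambda: dict(INDICATION_CATEGORIES))
    dedupe_mode: str = "earliest_per_patient"  # or "keep_all"
    seed: int = 0
    dayfirst: bool = False
    output_path: Optional[str] = None
    lookup_path: Optional[str] = None
    audit_path: Optional[str] = None
    existing_lookup: Optional[LookupTable] = None

    def __post_init__(self):
        if self.dedupe_mode not in ("earliest_per_patient", "keep_all"):
            raise ConfigurationError(f"unknown dedupe_mode {self.dedupe_mode!r}")
        if (self.output_path is not None and self.lookup_path is not None
                and Path(self.output_path).resolve() == Path(self.lookup_path).resolve()):
            raise ConfigurationError("output_path and lookup_path must differ")


@dataclass
class PipelineResult:
    clean: pd.DataFrame
    audit: AuditLog
    lookup: LookupTable
    dropped_columns: list[str]


# ---------------------------------------------------------------------------
# loading / stitching
# ---------------------------------------------------------------------------

def load_chunks(inputs: Sequence) -> list[pd.DataFrame]:
    """Load export chunks from paths/globs (CSV, all cells as strings)."""
    chunks = []
    for item in inputs:
        if isinstance(item, pd.DataFrame):
            chunks.append(item.astype(str).replace("nan", ""))
            continue
        paths = sorted(globmod.glob(str(item))) or [str(item)]
        for p in paths:
            chunks.append(pd.read_csv(p, dtype=str, keep_default_na=False,
                                      encoding="utf-8"))
    if not chunks:
        raise ConfigurationError("no input chunks found")
    return chunks


def apply_aliases(chunk: pd.DataFrame, alias_profiles: Sequence[dict]
                  ) -> pd.DataFrame:
    """Rename export headers to canonical names using whichever profile
    entries match; unmapped columns are preserved untouched."""
    renames = {}
    for profile in alias_profiles:
        for alias, canonical in profile.items():
            if alias in chunk.columns:
                renames[alias] = canonical
    return chunk.rename(columns=renames)


def stitch(chunks: Sequence[pd.DataFrame],
           audit: Optional[AuditLog] = None) -> pd.DataFrame:
    """Concatenate chunks into one table; columns are unioned and unknown
    columns preserved (and logged)."""
    if not chunks:
        raise ConfigurationError("stitch requires at least one chunk")
    table = pd.concat(list(chunks), axis=0, ignore_index=True, sort=False)
    table = table.fillna("")
    if audit is not None:
        for col in table.columns:
            if col not in RAW_COLUMNS:
                audit.add("-", col, "", "unmapped_column_preserved")
    return table


def drop_unused(table: pd.DataFrame,
                audit: Optional[AuditLog] = None) -> pd.DataFrame:
    """Drop columns where every observation is missing/empty."""
    empty = [c for c in table.columns
             if (table[c].astype(str).str.strip() == "").all()]
    if audit is not None:
        for c in empty:
            audit.add("-", c, "", "all_missing_column_dropped")
    return table.drop(columns=empty)


# ---------------------------------------------------------------------------
# per-row cleaning
# ---------------------------------------------------------------------------

def _get(row: dict, fld: str) -> str:
    v = row.get(fld, "")
    return "" if v is None else str(v)


def _put_cv(out: dict, audit: AuditLog, key, fld: str, raw: str,
            cv: num.CleanValue) -> None:
    out[fld] = cv.value
    if cv.recode_reason is not None:
        audit.add(key, fld, raw, "recoded_missing", cv.recode_reason)
    elif cv.provenance in (num.RANGE_MEAN, num.TEXT_EXTRACTED):
        audit.add(key, fld, raw, cv.provenance)


def clean_table(table: pd.DataFrame, config: PipelineConfig,
                audit: AuditLog) -> pd.DataFrame:
    """Run all cleaning stages over an aliased, anonymised, stitched table."""
    missing_cols = []
    if "anonymous_id" not in table.columns and ID_COLUMN not in table.columns:
        missing_cols.append(ID_COLUMN)
    if DATE_COLUMN not in table.columns:
        missing_cols.append(DATE_COLUMN)
    if missing_cols:
        raise ConfigurationError(
            f"mandatory columns missing after aliasing: {missing_cols}")

    from .textrules import default_rulesets
    rulesets = (default_rulesets() if config.rules_path is None
                else load_rulesets(config.rules_path))
    ncfg = config.numeric
    rows_out = []
    for i, row in enumerate(table.to_dict(orient="records")):
        out: dict = {}
        key = row.get("anonymous_id", row.get(ID_COLUMN, i))
        out["anonymous_id"] = key
        out[DATE_COLUMN] = _get(row, DATE_COLUMN)

        # demographics ----------------------------------------------------
        age = num.parse_number(_get(row, "age"), ncfg)
        out["age"] = age if age is not None else float("nan")
        sex_raw = _get(row, "sex").strip().lower()
        out["sex"] = _SEX_MAP.get(sex_raw, "")
        if sex_raw and out["sex"] == "":
            audit.add(key, "sex", sex_raw, "recoded_missing", num.UNPARSEABLE)

        h_raw, w_raw = _get(row, "height"), _get(row, "weight")
        h, w, flag = num.clean_height_weight(h_raw, w_raw, ncfg)
        if flag:
            audit.add(key, "height", f"{h_raw}/{w_raw}", "recoded",
                      num.TRANSPOSED_CORRECTED)
        out["height"] = h if h is not None else float("nan")
        out["weight"] = w if w is not None else float("nan")
        bmi, _ = num.compute_bmi(h_raw, w_raw, ncfg)
        _put_cv(out, audit, key, "bmi", f"{h_raw}/{w_raw}", bmi)

        # heart rate and rhythm --------------------------------------------
        hr_raw = _get(row, "heart_rate")
        _put_cv(out, audit, key, "heart_rate", hr_raw,
                num.clean_heart_rate(hr_raw, ncfg))
        rhythm_cls, bbb_cls = classify_rhythm(_get(row, "rhythm_text"), rulesets)
        out["rhythm"], out["bbb"] = rhythm_cls.level, bbb_cls.level

        # indications -------------------------------------------------------
        flags = flag_indications(_get(row, "indication_text"),
                                 config.indication_categories)
        for cat, val in flags.items():
            out[f"indication_{cat}"] = val

        # numeric measurements ----------------------------------------------
        for fld in ["ivsd", "lvpwd", "lvot_diameter", "mitral_e", "mitral_a",
                    "e_prime_septal", "e_prime_lateral", "e_over_a",
                    "e_over_e_prime", "asc_aorta_diameter",
                    "aortic_root_diameter", "aov_vmax", "aov_mean_gradient",
                    "aov_vti", "lvot_vti", "aov_area", "tr_vmax"]:
            raw = _get(row, fld)
            _put_cv(out, audit, key, fld, raw, num.clean_positive(raw, fld, ncfg))
        lavi = num.parse_number(_get(row, "lavi"), ncfg)
        out["lavi"] = lavi if lavi is not None else float("nan")

        # ejection fraction hierarchy ---------------------------------------
        measurements = {}
        for method, col in LVEF_METHOD_COLUMNS.items():
            raw = _get(row, col)
            if raw.strip():
                measurements[method] = num.clean_positive(raw, col, ncfg)
        out["lvef"] = num.select_lvef(measurements, ncfg).value

        # free-text sections -------------------------------------------------
        lv_text = _get(row, "lv_text")
        out["lv_size"] = classify(lv_text, rulesets["lv_size"]).level
        out["lv_function"] = classify(lv_text, rulesets["lv_function"]).level
        out["la_size"] = classify_la_size(_get(row, "la_text"), out["lavi"],
                                          config.la_thresholds, rulesets).level

        mitral_text = _get(row, "mitral_text")
        out["mitral_stenosis"] = classify(
            mitral_text, rulesets["mitral_stenosis"]).level
        out["mitral_regurgitation"] = classify_regurgitation(
            mitral_text, "mitral", rulesets).level
        out["mitral_annular_calcification"] = classify(
            mitral_text, rulesets["mitral_annular_calcification"]).level
        out["mitral_prolapse"] = classify(
            mitral_text, rulesets["mitral_prolapse"]).level
        out["any_mitral_calcification"] = any_mitral_calcification(
            out["mitral_annular_calcification"], out["mitral_stenosis"])

        aortic_text = _get(row, "aortic_text")
        out["aortic_stenosis"] = classify_aortic_stenosis(aortic_text, rulesets).level
        out["aortic_regurgitation"] = classify_regurgitation(
            aortic_text, "aortic", rulesets).level
        out["av_morphology"] = classify_av_morphology(aortic_text, rulesets).level
        out["dimensionless_index"] = dimensionless_index(
            out["lvot_vti"], out["aov_vti"]).value

        pulm_text = _get(row, "pulmonary_text")
        out["pulmonary_stenosis"] = classify(
            pulm_text, rulesets["pulmonary_stenosis"]).level
        out["pulmonary_regurgitation"] = classify_regurgitation(
            pulm_text, "pulmonary", rulesets).level

        tric_text = _get(row, "tricuspid_text")
        out["tricuspid_regurgitation"] = classify_regurgitation(
            tric_text, "tricuspid", rulesets).level
        rvsp_raw = _get(row, "rvsp")
        _put_cv(out, audit, key, "rvsp", rvsp_raw or tric_text,
                num.extract_rvsp(rvsp_raw, tric_text, ncfg))

        out["diastolic_function"] = diastolic_function(
            lvef=out["lvef"], mitral_e=out["mitral_e"],
            e_over_a=out["e_over_a"], e_over_e_prime=out["e_over_e_prime"],
            e_prime_septal=out["e_prime_septal"],
            e_prime_lateral=out["e_prime_lateral"],
            tr_vmax=out["tr_vmax"], lavi=out["lavi"],
            criteria=config.diastolic).level

        rv_text = _get(row, "rv_text")
        out["rv_size"] = classify(rv_text, rulesets["rv_size"]).level
        out["rv_function"] = classify(rv_text, rulesets["rv_function"]).level
        rows_out.append(out)

    clean = pd.DataFrame(rows_out)
    # only the typed record is exported; raw free text never leaves the pipeline
    cols = [c for c in CLEAN_COLUMNS if c in clean.columns]
    extra = [f"indication_{c}" for c in config.indication_categories
             if f"indication_{c}" not in cols]
    return clean[cols + extra] if extra else clean[cols]


# ---------------------------------------------------------------------------
# de-duplication
# ---------------------------------------------------------------------------

def dedupe_earliest(table: pd.DataFrame, audit: Optional[AuditLog] = None,
                    dayfirst: bool = False,
                    id_column: str = "anonymous_id") -> pd.DataFrame:
    """Keep the earliest study per patient.

    Ties on identical dates are broken by stable input order (first kept);
    rows with unparseable dates are excluded and logged.
    """
    dates = pd.to_datetime(table[DATE_COLUMN], errors="coerce",
                           dayfirst=dayfirst, format="mixed")
    bad = dates.isna()
    if audit is not None:
        for idx in table.index[bad]:
            audit.add(table.at[idx, id_column], DATE_COLUMN,
                      table.at[idx, DATE_COLUMN], "excluded_unparseable_date")
    kept = table[~bad].copy()
    kept_dates = dates[~bad]
    order = pd.DataFrame({"_id": kept[id_column], "_date": kept_dates,
                          "_pos": range(len(kept))})
    first = order.sort_values(["_id", "_date", "_pos"], kind="stable")
    winners = first.groupby("_id", sort=False).head(1)
    if audit is not None:
        dup_dates = first.groupby(["_id", "_date"]).size()
        for (pid, d), n in dup_dates.items():
            if n > 1:
                audit.add(pid, DATE_COLUMN, d.date().isoformat(),
                          "dedupe_tie_first_kept")
    result = kept.iloc[sorted(winners["_pos"])].reset_index(drop=True)
    return result


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run(config: PipelineConfig,
        chunks: Optional[Sequence[pd.DataFrame]] = None) -> PipelineResult:
    """Execute the full cleaning sequence; deterministic given config+seed."""
    audit = AuditLog()
    if chunks is None:
        chunks = load_chunks(config.inputs)
    aliased = [apply_aliases(c, config.alias_profiles) for c in chunks]
    table = stitch(aliased, audit)

    if ID_COLUMN not in table.columns:
        raise ConfigurationError(
            f"mandatory columns missing after aliasing: ['{ID_COLUMN}']")
    table, lookup = anonymize(table, existing=config.existing_lookup,
                              seed=config.seed)

    before = list(table.columns)
    table = drop_unused(table, audit)
    dropped = [c for c in before if c not in table.columns]

    clean = clean_table(table, config, audit)

    n_before = len(clean)
    if config.dedupe_mode == "earliest_per_patient":
        clean = dedupe_earliest(clean, audit, dayfirst=config.dayfirst)
    audit.add("-", "-", "", "row_reconciliation",
              f"in={n_before},out={len(clean)},removed={n_before - len(clean)}")

    if config.output_path:
        clean.to_csv(config.output_path, index=False, lineterminator="\n")
    if config.lookup_path:
        write_lookup(lookup, config.lookup_path, dataset_path=config.output_path)
    if config.audit_path:
        audit.write(config.audit_path)
    return PipelineResult(clean, audit, lookup, dropped)
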