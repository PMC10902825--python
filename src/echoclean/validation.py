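"""Validation protocol: sampled comparison against a gold standard.

A seeded random sample of studies is compared variable by variable against a
gold-standard table (in production, a clinician's reading of the clinical
report; in testing, the generator's ground truth).  For each variable the
percent agreement and Cohen's kappa are reported, and the indication flags
are summarised by their mean kappa.

Kappa is computed directly from the confusion matrix:
kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and p_e the
chance agreement implied by the marginal label frequencies.  Pairs with a
missing label on either side are dropped (their count is reported).  When the
two raters share a single label (p_e = 1) kappa is defined as 1 when
agreement is perfect and flagged undefined otherwise.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .schema import CATEGORICAL_VARIABLES, INDICATION_FLAG_COLUMNS

VALIDATION_VARIABLES = (list(CATEGORICAL_VARIABLES)
                        + ["any_mitral_calcification", "diastolic_function",
                           "sex", "age"])

def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip().lower() in {"", "nan"}


def _labels(seq) -> list:
    out = []
    for v in seq:
        if _is_missing(v):
            out.append(None)
            continue
        if isinstance(v, float) and v == int(v):
            v = int(v)  # 60.0 and 60 are the same label
        out.append(v if isinstance(v, bool) else str(v))
    return out


def sample_studies(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Simple random sample of n studies without replacement (seeded)."""
    if n > len(table):
        raise InputError(f"cannot sample {n} studies from {len(table)} rows")
    return table.sample(n=n, random_state=seed)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    n_used: int
    n_dropped_missing: int
    undefined: bool


def kappa_statistic(a: Sequence, b: Sequence, drop_missing: bool = True
                    ) -> KappaResult:
    """Cohen's kappa with full detail; raises on length mismatch."""
    if len(a) != len(b):
        raise InputError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    pairs = list(zip(_labels(a), _labels(b)))
    if drop_missing:
        kept = [(x, y) for x, y in pairs
                if not (_is_missing(x) or _is_missing(y))]
    else:
        kept = pairs
    dropped = len(pairs) - len(kept)
    n = len(kept)
    if n == 0:
        return KappaResult(float("nan"), float("nan"), float("nan"), 0,
                           dropped, True)
    p_o = sum(1 for x, y in kept if x == y) / n
    ma = Counter(x for x, _ in kept)
    mb = Counter(y for _, y in kept)
    p_e = sum(ma[l] * mb.get(l, 0) for l in ma) / (n * n)
    if p_e >= 1.0:
        # a single shared label: perfect agreement is kappa 1, anything else
        # is undefined
        if p_o == 1.0:
            return KappaResult(1.0, p_o, p_e, n, dropped, False)
        return KappaResult(float("nan"), p_o, p_e, n, dropped, True)
    return KappaResult((p_o - p_e) / (1.0 - p_e), p_o, p_e, n, dropped, False)


def cohen_kappa(a: Sequence, b: Sequence) -> float:
    """Cohen's kappa in [-1, 1] (missing pairs dropped)."""
    return kappa_statistic(a, b).kappa


@dataclass
class ValidationReport:
    """Per-variable agreement versus the gold standard (plus the mean kappa
    across indication categories)."""

    table: pd.DataFrame  # variable, n_compared, proportion_agree_pct, kappa
    indications_mean_kappa: float
    sample_seed: int
    sample_size: int

    def to_text(self) -> str:
        lines = [f"Validation report (n={self.sample_size}, "
                 f"seed={self.sample_seed})",
                 f"{'Variable':34s} {'n':>5s} {'Agree %':>8s} {'Kappa':>7s}"]
        for _, r in self.table.iterrows():
            k = "nan" if math.isnan(r["kappa"]) else f"{r['kappa']:.2f}"
            lines.append(f"{r['variable']:34s} {int(r['n_compared']):5d} "
                         f"{r['proportion_agree_pct']:8.1f} {k:>7s}")
        lines.append(f"Mean kappa across indication categories: "
                     f"{self.indications_mean_kappa:.2f}")
        return "\n".join(lines)


def validate(clean: pd.DataFrame, gold: pd.DataFrame,
             variables: Optional[Sequence[str]] = None,
             n: Optional[int] = None, seed: int = 0,
             key: Sequence[str] = ("anonymous_id", "study_date")
             ) -> ValidationReport:
    """Compare cleaned output against a gold standard on a seeded sample.

    The two tables are joined on ``key``; each listed variable (plus every
    shared indication flag) is scored by percent agreement and Cohen's kappa
    over non-missing pairs.
    """
    if variables is None:
        variables = [v for v in VALIDATION_VARIABLES
                     if v in clean.columns and v in gold.columns]
    else:
        for v in variables:
            if v not in clean.columns or v not in gold.columns:
                raise InputError(f"variable {v!r} absent from clean or gold table")
    key = list(key)
    merged = clean.merge(gold, on=key, suffixes=("_clean", "_gold"), how="inner")
    if n is None:
        n = len(merged)
    sampled = sample_studies(merged, n, seed)

    rows = []
    for v in variables:
        a = sampled[f"{v}_clean"] if f"{v}_clean" in sampled else sampled[v]
        b = sampled[f"{v}_gold"] if f"{v}_gold" in sampled else sampled[v]
        res = kappa_statistic(list(a), list(b))
        agree = 100.0 * res.p_observed if res.n_used else float("nan")
        rows.append({"variable": v, "n_compared": res.n_used,
                     "proportion_agree_pct": agree, "kappa": res.kappa})

    ind_kappas = []
    flags = [c for c in INDICATION_FLAG_COLUMNS
             if f"{c}_clean" in sampled.columns or c in sampled.columns]
    for c in flags:
        a = sampled[f"{c}_clean"] if f"{c}_clean" in sampled else sampled[c]
        b = sampled[f"{c}_gold"] if f"{c}_gold" in sampled else sampled[c]
        res = kappa_statistic(list(a), list(b))
        if not math.isnan(res.kappa):
            ind_kappas.append(res.kappa)
        rows.append({"variable": c, "n_compared": res.n_used,
                     "proportion_agree_pct": 100.0 * res.p_observed,
                     "kappa": res.kappa})
    mean_k = float(np.mean(ind_kappas)) if ind_kappas else float("nan")
    return ValidationReport(pd.DataFrame(rows), mean_k, seed, n)
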