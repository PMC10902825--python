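# Methods

## The cleaning model

`echoclean` implements a deterministic, auditable protocol for converting a
semi-structured echocardiography PACS export into an analysable dataset.
The protocol has four parts: numeric plausibility recoding, ordered
phrase-rule classification of free text, derived clinical variables, and a
kappa-based validation loop. Everything is a pure function of the input
table and the configuration; a fixed seed makes the de-identification and
any sampling reproducible byte for byte.

### Stage order

Cleaning runs in a fixed sequence: load and stitch chunks → resolve column
aliases → anonymise identifiers → drop columns that are entirely missing →
demographics and BMI → indications → rhythm and heart rate → LV numeric
measurements → LV/LA free text → mitral valve → aortic valve → pulmonary
valve → tricuspid valve → RVSP → diastolic function → RV free text →
export. The export contains only the typed record; raw free text never
leaves the pipeline. De-duplication to the earliest study per patient
happens only at export (repeat studies are cleaned like any other), with
ties on identical dates broken by stable input order and unparseable dates
excluded with an audit entry.

## Numeric recoding

- **BMI** = weight / height² (kg/m²). Values ≥70 or ≤14 are recoded missing
  (both bounds excluded, as printed in the protocol). A height above 3 is
  read as centimetres. A pair with height in [20, 250] and weight in
  [1.2, 2.2] is treated as a height/weight transposition, swapped back and
  flagged — this automates what was a manual correction step; the flag
  surfaces the rows for review. The transposition check runs on the parsed
  raw values *before* the centimetre heuristic, since converting a
  transposed "height" of 80 to 0.8 m first would hide the pattern.
- **Heart rate**: a range `a–b` (hyphen, en-dash, or "to") becomes the mean
  of its endpoints; results strictly above 200 bpm are excluded ("over
  200" read as a strict bound).
- **Non-positive exclusion**: for measurements that cannot be zero or less
  (wall thicknesses, diameters, velocities, gradients, VTIs, valve area,
  mitral inflow indices), any parsed value ≤0 is recoded missing with
  reason `nonpositive`.
- **LVEF**: one value is selected by method hierarchy — modified biplane,
  modified apical four chamber, modified apical two chamber, Teichholz 2D,
  M-mode cube, M-mode — after each candidate passes the non-positive rule.
  The historical misspelling "Teicholz" is normalised to Teichholz.
- **RVSP**: the numeric field wins; otherwise the *last* number immediately
  preceding "mmHg" in the tricuspid/RVSP text is extracted (summary
  statements tend to close a section). Text-extracted values carry
  provenance `text_extracted` so they can be audited, replacing the visual
  check used when this was done by hand.

Every missing value produced by cleaning carries a reason
(`out_of_range`, `nonpositive`, `unparseable`, or an empty source), and
every recode is a line in the audit log, so injected corruption counts can
be reconciled exactly.

## Phrase-rule classification

Rules are data, not code: each variable has an ordered list of patterns in
`data/default_rules.yaml`, evaluated by ascending priority with first match
wins and a per-variable default when nothing fires. Two kinds exist:
*direct* rules (consecutive-phrase mini-regexes over the whole text) and
*catch-all* rules (whole-word tokens that must co-occur within one
sentence; sentences are split on `.`, `;` and newlines — report sections
are short clause lists, so this narrow delimiter set suffices). Direct
rules are required to precede all catch-alls; this ordering is what makes
"mild regurgitation and moderate stenosis" grade mild — the direct match
happens before the moderate/regurgitation co-occurrence can fire. Matching
is case-insensitive over text whose hyphens are normalised to spaces, so
"mild-to-moderate" and "mild to moderate" are one phrase; normalisation
preserves character positions so the audited matched span is always a
substring of the original text.

Variable-specific logic:

- **Aortic stenosis**: replacement terms (AVR, prosthesis, valve
  replacement…) are checked first — a prosthetic valve is exogenous and
  graded AVR regardless of other wording. Explicit severity terms come
  next, then thickened/sclerosis wording grades *sclerosis*, then the
  default none. Severity outranks sclerosis so "severely thickened
  leaflets, severe aortic stenosis" grades severe.
- **Negation** ("no stenosis", "no regurgitation", "trivial/trace
  regurgitation") is handled by explicit rules evaluated before the
  positive severity rules; the original protocol had no negation mechanism,
  so this is a deliberate hardening.
- **Aortic valve morphology**: "bicuspid" → bicuspid; unicuspid or
  quadricuspid → the record is marked EXCLUDE for morphology analyses
  (rare morphologies risk identifiability); anything else — including an
  unremarked valve — is tricuspid, because a bicuspid valve is clinically
  significant and would not go unreported.
- **Rhythm** is a priority list (artificially paced > SVT > atrial flutter
  > atrial fibrillation > heart block > sinus > other > uncertain); bundle
  branch block is extracted independently as left/right/unspecified/none.
- **LA size** prefers the free-text grading; when only the indexed volume
  is available it is binned at ≤34 / ≤41 / ≤48 / >48 mL/m² (configurable
  `LaThresholds`, defaults from the chamber-quantification guideline).
- **Indications** are independent binary flags per category; a study can
  match several. The shipped category list (murmur, valve assessment,
  heart failure, atrial fibrillation, endocarditis, preoperative) is a
  configurable starting point, not a canonical taxonomy.
- Intermediate grades (mild-to-moderate, moderate-to-severe) are first-class
  levels; `schema.COLLAPSE_INTERMEDIATE` maps them onto the four-grade
  scale for analyses that need it.

The default rule file is meant to be copied and re-tuned: classify, review
the audit log, edit the YAML, re-validate — the same iterative loop used to
develop rules against a real laboratory's dialect.

## Derived variables

- **Dimensionless index** = LVOT VTI / AoV VTI; missing if either input is.
- **Any mitral calcification** = annular calcification present OR mitral
  stenosis above none.
- **Diastolic function**: the two-arm guideline tree, with "normal LVEF"
  defined as >50% (the hierarchy-selected LVEF). Normal-EF arm: four
  criteria — average E/e′ > 14, septal e′ < 7 cm/s or lateral e′ < 10 cm/s,
  TR Vmax > 2.8 m/s, LAVi > 34 mL/m² — counted over those evaluable; more
  than half positive → *dysfunction* (emitted ungraded in this arm),
  fewer → normal, exactly half → indeterminate, fewer than two evaluable →
  not assessable. Reduced-EF arm: E/A ≤ 0.8 with E ≤ 50 cm/s → grade I;
  E/A ≥ 2 → grade III; the intermediate band is resolved by the E/e′, TR
  and LAVi vote (majority positive → grade II). Missing LVEF → not
  assessable. All thresholds live in `DiastolicCriteria`; only the >50%
  split is fixed by the protocol itself. Special-case pathways of the full
  guideline (atrial fibrillation, annular-calcification caveats) are out of
  scope. The tree is monotone: flipping any criterion negative→positive
  never moves a call toward normal, and withholding an input can coarsen a
  call to indeterminate/not assessable but never flip it.

## De-identification

Each unique true identifier receives a random 10-character ID over an
unambiguous alphabet (uppercase letters and digits minus O/0/I/1 — a
transcription-safety choice; the protocol requires only "10 characters").
The mapping is bijective and stable: re-encountering a known identifier
returns its existing ID, and collisions are resolved by redrawing. The
lookup table must be written to a different path than the dataset
(enforced). Seeded randomness keeps tests reproducible; study dates are
retained, and k-anonymity of quasi-identifiers is out of scope.

## Validation

A seeded simple random sample (the protocol used sets of 100 studies) is
compared variable by variable against a gold standard. Per variable:
percent agreement and unweighted Cohen's kappa κ = (p₀ − pₑ)/(1 − pₑ),
computed from the confusion matrix with missing-on-either-side pairs
dropped (their count reported); when both raters use one shared label
(pₑ = 1), κ is 1 under perfect agreement and flagged undefined otherwise.
Weighted kappa is deliberately not the default despite the ordinal grades,
matching the protocol; the indication flags are scored per category and
summarised by their mean kappa. Iterating rule edits against repeated
validation rounds is supported by re-running `validate` after editing the
rule YAML.

## The synthetic generator

`GeneratorConfig` defines the study conditions: 500 studies by default,
10% repeat-study rate (repeats strictly later in time, making
earliest-study selection testable), free text instantiated from a phrase
bank with 5% character-level typos on non-keyword tokens, 5% per-field
missingness on numeric fields, heart-rate ranges in 10% of studies,
heart rates above 200 bpm in 0.5%, non-positive measurement values in 0.2%
per injectable field, height/weight transpositions in 0.2% (the clinical
dataset's observed prevalence was of that order), BMI-extreme pairs in
0.2%, and centimetre-formatted heights in 10%. Exports are split into
three chunks over two alias profiles emulating report versions. Level
prevalences approximate a general echocardiography service (e.g. ~45% no
aortic stenosis, ~18% sclerosis, ~4% replaced valves; ~70% sinus rhythm,
15% atrial fibrillation).

The ground truth stores, per study and variable, the value a *correct*
cleaning run should produce given the corruptions actually injected — an
injected non-positive IVSd has expected value missing — plus a corruption
log whose realised counts the pipeline's audit log is reconciled against.
Typos never touch rule-keyword tokens by default, so round-trip recovery
measures rule coverage rather than luck; the `adversarial` flag corrupts
one keyword token per affected section at a configured rate (default 5%)
for robustness testing. Expected diastolic grade and the
any-mitral-calcification flag are computed through the package's own
derived-variable functions (they test plumbing, not the tree itself, which
has its own direct tests); all text-classification truths are sampled
*before* any phrase is rendered and are therefore independent of the
classifier.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: genuine narrative variation beyond the phrase
bank, misspellings of clinical keywords in routine (non-adversarial) text,
inconsistent units other than cm/m heights, contradictory statements
within a report, and the true prevalence structure of any particular
service. A real deployment still requires the iterative rule-tuning and
EHR-validation loop; the synthetic results certify the machinery, not any
one laboratory's phrase inventory.

## Numerical and design choices

- Decimal commas are off by default (`NumericRuleConfig.decimal_comma`);
  the target exports use decimal points.
- Date parsing accepts ISO and (configurably) day-first dialects.
- Problem sizes used by the shipped tests and the acceptance script —
  round trips at 150–400 studies, robustness at 1,000, de-identification
  at 10,000 patients, 1,000 random sequences for the kappa oracle — were
  chosen to give stable statistics at interactive runtimes.
- The kappa implementation is the package's own (the formula is part of
  the validation contract, including the missing-pair and degenerate-label
  policies); scikit-learn's `cohen_kappa_score` serves as an independent
  cross-check in the test suite only.

## Known limitations

English-language, phrase-bank-style reports only; no statistical or neural
NLP, no spelling correction. The categorical field preference (use a true
categorical column when the report provides one) is expressed through
column aliasing rather than a separate merge step. Kappa treats grades as
nominal (unweighted default). Linkage to administrative or outcome data,
and anything requiring the original clinical database, is out of scope.
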