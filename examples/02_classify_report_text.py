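"""Classify free-text report fragments with the shipped phrase rules.

Shows the ordered-rule behaviour that makes the grading safe: direct
wordings always beat sentence-level catch-alls, replacement terms beat
severity terms, and thickening without a severity term grades as sclerosis.
"""

import echoclean as ec

examples = [
    ("Systolic function appears within normal limits", "lv_function"),
    ("Moderate decrease in systolic function", "lv_function"),
    ("mild regurgitation and moderate stenosis", "aortic_regurgitation"),
    ("There is moderate eccentric regurgitation.", "aortic_regurgitation"),
    ("valve is thickened with no significant gradient", "aortic_stenosis"),
    ("severely thickened leaflets, severe aortic stenosis", "aortic_stenosis"),
    ("mechanical AVR in situ", "aortic_stenosis"),
]

rulesets = ec.default_rulesets()
for text, var in examples:
    cls = ec.classify(text, rulesets[var])
    print(f"{var:22s} {text!r}\n{'':22s} -> {cls.level:18s} "
          f"(matched: {cls.matched_span!r})")

rhythm, bbb = ec.classify_rhythm("AF with LBBB")
print(f"rhythm field 'AF with LBBB' -> {rhythm.level} / {bbb.level}")
# The matched span is the audit trail: every classification can be traced
# back to the exact fragment of report text that triggered it.
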