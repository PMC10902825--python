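"""Validate cleaned output against a gold standard with Cohen's kappa.

Cleans a synthetic export whose keyword tokens are adversarially corrupted
in 5% of sections, then scores every report variable against the generator's
ground truth on a seeded 100-study sample — the same protocol a laboratory
would run against its electronic health record.
"""

import echoclean as ec
from echoclean.pipeline import PipelineConfig, run
from echoclean.validation import validate

cfg = ec.GeneratorConfig(n_studies=500, seed=21, adversarial=True,
                         adversarial_keyword_rate=0.05)
chunks, gt = ec.generate_export(cfg)
result = run(PipelineConfig(dedupe_mode="keep_all"), chunks=chunks)
gold = gt.gold_table(result.lookup)

report = validate(result.clean, gold, n=100, seed=1)
print(report.to_text())
# Agreement below 100% here reflects the injected keyword corruption, not
# rule gaps: with corruption disabled every variable scores kappa 1.0.
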