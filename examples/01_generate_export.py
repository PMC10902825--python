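"""Generate a synthetic echocardiography PACS export with ground truth.

Builds a 50-study export split over three CSV chunks (two report versions
with different column headers), plus the hidden ground-truth table and the
corruption log, and prints what was injected.
"""

from pathlib import Path

import echoclean as ec

out_dir = Path("scratch/example_export")
cfg = ec.GeneratorConfig(n_studies=50, seed=42, n_chunks=3)
chunks, gt = ec.generate_export(cfg)
paths = ec.write_chunks(chunks, out_dir)
gt.write(out_dir)

print(f"wrote {len(paths)} chunks:")
for p in paths:
    header = p.read_text().splitlines()[0]
    print(f"  {p.name}: {len(header.split(','))} columns, "
          f"first headers {header.split(',')[:3]}")
print(f"ground truth rows: {len(gt.truth)}")
print("injected corruptions by kind:")
if len(gt.corruptions):
    print(gt.corruptions.groupby("kind").size().to_string())
else:
    print("  (none)")
# Each chunk is one 'report version': chunk 1 renames e.g. heart_rate to
# 'HR (bpm)'.  The ground truth holds the value a correct cleaning run
# should recover for every output variable.
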