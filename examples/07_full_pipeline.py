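"""The controlling pipeline: all analyses, static pages, run index.

Writes three synthetic structures, processes them, and reports the
pages generated. Equivalent CLI:

    structsum fixtures --out fx
    structsum run --list files.txt --out pipeline_out --seed 1
"""

import tempfile
from pathlib import Path

from structsum import fixtures as fx
from structsum.config import Config
from structsum.report import check_links, run_pipeline

tmp = Path(tempfile.mkdtemp(prefix="structsum_demo_"))
inputs = []
for name, text in (("helix.pdb", fx.make_ideal_helix(12)),
                   ("hairpin.pdb", fx.make_beta_hairpin()),
                   ("toy.pdb", fx.make_toy_complex())):
    path = tmp / name
    path.write_text(text)
    inputs.append(path)

out = tmp / "out"
cfg = Config()
cfg.seed = 1
records = run_pipeline(inputs, out, cfg)

for r in records:
    status = "ok" if r.error is None else f"ERROR: {r.error}"
    print(f"{r.code}  {Path(r.source).name:12s} {status}")
n_pages = len(list(out.rglob("*.html")))
print(f"\n{n_pages} HTML pages under {out}")
print(f"broken internal links: {len(check_links(out))}")
print("index.html lists the run; all_runs.html accumulates every prior "
      "run via the append-only runs.tsv registry.")
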