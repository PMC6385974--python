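"""One orchestrated run: filter -> normalize -> covariate selection ->
max-score selection -> DE (both trait codings) -> restricted FDR -> GLMM.

Writes every stage output plus a manifest (config, per-stage checksums,
row/gene counts) and a human-readable report; identical config + seed give
byte-identical result tables. Equivalent shell command:

    confoundr run --config run.yaml --out results/
"""

import tempfile
from pathlib import Path

from confoundr import GeneSet, SimConfig, generate, run_all

cfg = SimConfig(seed=6, n_genes=500, n_de_genes=15)
cm, samples, truth = generate(cfg)
panel = GeneSet("neuro_panel", frozenset(
    list(truth.de_genes.gene[:8]) + list(cm.gene_ids[:120])
))

with tempfile.TemporaryDirectory() as out:
    manifest = run_all(cm, samples, out, gene_sets=[panel],
                       config={"glmm_alpha": 0.01})
    print((Path(out) / "report.txt").read_text())
    print("stage outputs:", ", ".join(sorted(p.name for p in Path(out).iterdir())))
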