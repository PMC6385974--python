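"""Low-count filtering and between-sample normalization.

The q35 rule drops genes whose 75th-percentile raw count falls below the
35% quantile of all genes' 75th percentiles; TMM factors correct library
sizes for composition bias and median-of-ratios size factors feed the PCA
used in covariate selection. RPKM values are exploratory only.
"""

import numpy as np

from confoundr import SimConfig, generate, q35_filter, rpkm, size_factors, tmm_factors

cm, samples, _ = generate(SimConfig(seed=1))

filtered, rep = q35_filter(cm)
print(f"q35 threshold: {rep.q35:.1f} "
      f"(a gene's 75th-percentile count must reach this to be kept)")
print(f"genes: {rep.n_before} -> {rep.n_after}")

nf = tmm_factors(filtered)
sf = size_factors(filtered)
print(f"TMM factors: min {nf.tmm.min():.3f}, max {nf.tmm.max():.3f} "
      f"(geometric mean {np.exp(np.mean(np.log(nf.tmm))):.6f})")
print(f"size factors: min {sf.size_factor.min():.3f}, max {sf.size_factor.max():.3f}")

vals = rpkm(filtered, nf)
print(f"median RPKM of kept genes: {np.median(vals):.2f} "
      f"(length- and depth-normalized expression, for exploration)")
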