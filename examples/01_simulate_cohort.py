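"""Generate a synthetic post-deployment cohort and inspect its design.

The default configuration mirrors the repeated-measures blood-draw design:
85 subjects of whom 58 give one sample, 21 two and 6 three (118 measurements),
a PCL-M symptom score splitting the cohort roughly 58 control / 27 symptoms
at the >=34 cutoff, batch/blood/QC covariates with planted expression
loadings, 50 trait-linked genes and subject-level random intercepts.
"""

from confoundr import SimConfig, generate

cfg = SimConfig(seed=1)
cm, samples, truth = generate(cfg)

per_subject = samples.data.groupby("subject_id")
sizes = per_subject.size().value_counts().sort_index()
peak = per_subject["pcl_m"].max()

print(f"cohort: {cm.n_genes} genes x {cm.n_samples} measurements "
      f"from {len(per_subject)} subjects")
print("measurements per subject:", {int(k): int(v) for k, v in sizes.items()})
print(f"subjects with peak PCL-M >= 34 (symptoms group): {(peak >= 34).sum()}")
print(f"planted trait-linked genes: {len(truth.de_genes)} "
      f"(log2 fold-change {cfg.de_log2fc})")
print("covariates:", ", ".join(samples.covariates))
# The counts are NB-distributed around a log-linear mean, so every analysis
# stage downstream can be validated against this known ground truth.
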