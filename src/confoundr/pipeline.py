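"""End-to-end orchestration: filter -> normalize -> covariate selection ->
per-subject measurement selection -> differential expression (both trait
codings) -> restricted FDR -> repeated-measures GLMM, with a run manifest.

A single config dict (typically loaded from YAML) names every threshold:
q35 quantile, screen p (0.1), model-comparison p (0.001), PCL-M dichotomy
(34), GLMM candidate alpha (0.05), permutation count (5) and PC cap (10).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covsel as _covsel
from .de import SYMPTOM_THRESHOLD, restricted_fdr, run_de, select_max_pcl, volcano_table
from .glmm import candidate_genes, compare_with_single, run_glmm
from .io import (
    CountMatrix,
    GeneSet,
    SampleTable,
    read_counts,
    read_covariate_spec,
    read_gene_set,
    read_sample_table,
    write_results,
)
from .normalize import q35_filter, size_factors, tmm_factors

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "q35_quantile": 0.35,
    "n_perm": 5,
    "max_pcs": 10,
    "screen_p": 0.1,
    "model_p": 0.001,
    "prune_threshold": 0.8,
    "pcl_threshold": SYMPTOM_THRESHOLD,
    "glmm_alpha": 0.05,
    "glmm_nodes": 8,
    "discordance_log10_ratio": 1.0,
    "pca_log": True,
    "seed": 1,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_all(
    cm: CountMatrix,
    st: SampleTable,
    out_dir: str | Path,
    gene_sets: list[GeneSet] | None = None,
    config: dict | None = None,
) -> RunManifest:
    """Execute the whole analysis chain, writing every stage output.

    Outputs under ``out_dir``: filter_report.tsv, factors.tsv, covsel/
    (screen_table.tsv, per_pc_selected.tsv, final_set.txt), de_continuous.tsv,
    de_discrete.tsv, volcano_*.tsv, glmm_results.tsv, discordance.tsv,
    manifest.json and report.txt.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]))
    gene_sets = gene_sets or []

    st = st.aligned_to(cm)
    manifest.add_stage("input", n_genes=cm.n_genes, n_measurements=cm.n_samples,
                       n_subjects=int(st.data["subject_id"].nunique()))

    # 1. low-expression filter
    fcm, rep = q35_filter(cm, quantile=cfg["q35_quantile"])
    pd.DataFrame(
        {"gene": cm.gene_ids, "p75": rep.per_gene_p75, "kept": rep.keep_mask}
    ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
    manifest.add_stage("q35_filter", q35=rep.q35, n_before=rep.n_before, n_after=rep.n_after,
                       checksum=_sha256(out / "filter_report.tsv"))

    # 2. normalization factors
    nf_tmm = tmm_factors(fcm)
    nf_mor = size_factors(fcm)
    pd.DataFrame(
        {
            "sample_id": fcm.sample_ids,
            "lib_size": nf_tmm.lib_size,
            "tmm": nf_tmm.tmm,
            "size_factor": nf_mor.size_factor,
        }
    ).to_csv(out / "factors.tsv", sep="\t", index=False, float_format="%.12g")
    manifest.add_stage("normalize", checksum=_sha256(out / "factors.tsv"))

    # 3. covariate selection on all measurements
    sel_res = _covsel.select_covariates(
        fcm, st, n_perm=cfg["n_perm"], seed=cfg["seed"], max_pcs=cfg["max_pcs"],
        screen_p=cfg["screen_p"], model_p=cfg["model_p"],
        prune_threshold=cfg["prune_threshold"], log=cfg["pca_log"],
    )
    cov_dir = out / "covsel"
    cov_dir.mkdir(exist_ok=True)
    sel_res.screen_table.to_csv(cov_dir / "screen_table.tsv", sep="\t", index=False,
                                float_format="%.12g")
    pd.DataFrame(
        [(pc, c) for pc, cc in sel_res.per_pc_selected.items() for c in cc],
        columns=["pc", "covariate"],
    ).to_csv(cov_dir / "per_pc_selected.tsv", sep="\t", index=False)
    (cov_dir / "final_set.txt").write_text("\n".join(sel_res.final_set) + "\n")
    manifest.add_stage(
        "covariate_selection", k_selected=sel_res.pcs.k_selected,
        final_set=sel_res.final_set, checksum=_sha256(cov_dir / "screen_table.tsv"),
    )
    covariates = sel_res.final_set

    # 4. one measurement per subject
    st_sel = select_max_pcl(st)
    cm_sel = fcm.subset_samples(st_sel.sample_ids)
    manifest.add_stage("select_max_pcl", n_before=cm.n_samples, n_after=cm_sel.n_samples)

    # 5. differential expression, both trait codings, with restricted FDR
    de_tables: dict[str, pd.DataFrame] = {}
    for mode in ("continuous", "discrete"):
        de = run_de(cm_sel, st_sel, mode, covariates=covariates, gene_sets=gene_sets,
                    threshold=cfg["pcl_threshold"])
        write_results(de, out / f"de_{mode}.tsv")
        write_results(volcano_table(de), out / f"volcano_{mode}.tsv")
        de_tables[mode] = de
        manifest.add_stage(
            f"de_{mode}", n_genes=len(de), n_converged=int(de["converged"].sum()),
            checksum=_sha256(out / f"de_{mode}.tsv"),
        )

    # 6. repeated-measures sensitivity analysis on continuous-model hits
    cand = candidate_genes(de_tables["continuous"], alpha=cfg["glmm_alpha"])
    if cand is None:
        manifest.warnings.append("no GLMM candidates at the configured alpha")
        glmm_table = pd.DataFrame(
            columns=["gene", "coef", "sigma_u", "dispersion", "p", "loglik",
                     "converged", "degenerate"]
        )
    else:
        glmm_table = run_glmm(fcm, st, covariates=covariates, candidates=cand,
                              n_nodes=cfg["glmm_nodes"])
    write_results(glmm_table, out / "glmm_results.tsv")
    disc = compare_with_single(de_tables["continuous"], glmm_table,
                               log10_ratio_threshold=cfg["discordance_log10_ratio"])
    write_results(disc, out / "discordance.tsv")
    manifest.add_stage("glmm", n_candidates=len(glmm_table),
                       n_discordant=int(disc["discordant"].sum()) if len(disc) else 0,
                       checksum=_sha256(out / "glmm_results.tsv"))

    report_text = report(manifest, de_tables, glmm_table, disc, gene_sets)
    (out / "report.txt").write_text(report_text)
    manifest.write(out / "manifest.json")
    return manifest


def report(
    manifest: RunManifest,
    de_tables: dict[str, pd.DataFrame],
    glmm_table: pd.DataFrame,
    discordance: pd.DataFrame,
    gene_sets: list[GeneSet],
    truth=None,
    top_n: int = 10,
) -> str:
    """Human-readable run summary: top genes per model, covsel, discordance.

    With a SimTruth object, recovery metrics (sensitivity of the top-100
    ranking for planted genes) are appended.
    """
    lines: list[str] = ["confoundr run summary", "=" * 40]
    for stage in manifest.stages:
        extras = {k: v for k, v in stage.items() if k not in ("stage", "checksum")}
        lines.append(f"[{stage['stage']}] " + ", ".join(f"{k}={v}" for k, v in extras.items()))
    set_cols = [f"fdr_{gs.name}" for gs in gene_sets]
    for mode, de in de_tables.items():
        lines.append("")
        lines.append(f"Top genes, {mode.upper()} model (gene, FC, p, BH-FDR all"
                     + "".join(f", BH-FDR {gs.name}" for gs in gene_sets) + "):")
        if de.empty or de["p"].isna().all():
            lines.append("  zero tested genes")
            continue
        top = de.nsmallest(top_n, "p")
        for _, r in top.iterrows():
            row = f"  {r['gene']}\t{mode[:4].upper()}\tFC={r['fc']:.3g}\tp={r['p']:.3g}\tfdr_all={r['fdr_all']:.3g}"
            for c in set_cols:
                v = r.get(c, np.nan)
                row += f"\t{c}={'NA' if pd.isna(v) else format(v, '.3g')}"
            lines.append(row)
    if len(discordance):
        n_disc = int(discordance["discordant"].sum())
        lines.append("")
        lines.append(f"Repeated-measures check: {len(discordance)} genes refit, "
                     f"{n_disc} discordant")
        for _, r in discordance[discordance["discordant"]].iterrows():
            lines.append(f"  {r['gene']}: p_single={r['p_single']:.3g} p_glmm={r['p_glmm']:.3g}")
    if truth is not None and len(truth.de_genes):
        de = de_tables.get("discrete", next(iter(de_tables.values())))
        top100 = set(de.nsmallest(min(100, len(de)), "p")["gene"])
        planted = set(truth.de_genes["gene"]) & set(de["gene"])
        if planted:
            sens = len(planted & top100) / len(planted)
            lines.append("")
            lines.append(f"Recovery: {sens:.1%} of {len(planted)} planted genes in top 100 by p")
    return "\n".join(lines) + "\n"


def run_from_paths(
    counts_path: str | Path,
    samples_path: str | Path,
    covariate_spec_path: str | Path,
    out_dir: str | Path,
    gene_set_paths: list[str | Path] | None = None,
    config: dict | None = None,
) -> RunManifest:
    """File-based entry point used by the command line."""
    cm = read_counts(counts_path)
    spec = read_covariate_spec(covariate_spec_path)
    st = read_sample_table(samples_path, spec)
    gene_sets = []
    for p in gene_set_paths or []:
        try:
            gene_sets.append(read_gene_set(p))
        except FileNotFoundError:
            raise RuntimeError(f"restricted-FDR stage: gene-set file {p} not found") from None
    return run_all(cm, st, out_dir, gene_sets=gene_sets, config=config)
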