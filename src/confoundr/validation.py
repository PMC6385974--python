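"""Simulation studies that exercise the pipeline under known truth.

Each function regenerates its cohorts from a seed, runs the relevant stage(s)
of the analysis and returns summary statistics: type-I error calibration,
confounding-induced inflation and its rescue by covariate selection,
recovery of planted confounders, random-intercept estimation across a
variance ladder, and the behaviour of permutation-calibrated PC selection
under null and structured data. The defaults are the cohort design the
package emulates (85 subjects, 58/21/6 repeat pattern, NB dispersion 0.1).
"""

from __future__ import annotations

import numpy as np

from .covsel import select_covariates, select_num_pcs
from .de import run_de, select_max_pcl
from .design import build_design
from .glmm import fit_nb_glmm
from .nbglm import fit_nb
from .normalize import q35_filter, size_factors, tmm_factors
from .simulate import CovariateSim, SimConfig, generate, null_config

STUDY_COVARIATES = [
    "batch", "neutrophil_count", "wbc_count", "gc_pct",
    "mapped_pct", "nonexonic_pct", "dedup_pct",
]


def cohort_reduction(seed: int = 1) -> tuple[int, int]:
    """Measurements before and after per-subject highest-score selection."""
    _, st, _ = generate(SimConfig(seed=seed, n_genes=5, n_de_genes=0))
    sel = select_max_pcl(st)
    return len(st.data), len(sel.data)


def _null_rate(seed: int, n_genes: int, covariates: list[str], confounding: float) -> tuple[int, int]:
    # sigma_u = 0: with one measurement per subject a random intercept is
    # indistinguishable from extra (lognormal) observation noise, which the
    # NB likelihood cannot represent, so a calibration check of the NB test
    # must generate NB-distributed nulls
    cfg = null_config(SimConfig(seed=seed, n_genes=n_genes, sigma_u=0.0))
    if confounding > 0:
        cfg.confounded_covariate = "batch"
        cfg.confounding = confounding
    cm, st, _ = generate(cfg)
    fcm, _ = q35_filter(cm)
    sel = select_max_pcl(st)
    de = run_de(fcm.subset_samples(sel.sample_ids), sel, "discrete", covariates=covariates)
    ok = de["p"].notna()
    return int((de.loc[ok, "p"] < 0.05).sum()), int(ok.sum())


def null_calibration(seeds=(101, 102, 103), n_genes: int = 2000) -> float:
    """Pooled p<0.05 rate of the discrete NB model on clean null cohorts.

    The model adjusts for the generative nuisance covariates, mirroring how
    the pipeline is used; with no trait effect planted the rate should sit
    at the nominal 5%.
    """
    hits = total = 0
    for s in seeds:
        h, n = _null_rate(s, n_genes, STUDY_COVARIATES, confounding=0.0)
        hits, total = hits + h, total + n
    return hits / total


def confounding_rescue(seeds=(201, 202, 203), n_genes: int = 2000) -> dict:
    """Type-I rates on batch-confounded null cohorts, with and without
    adjustment for the covariates the selection procedure picks."""
    h0 = n0 = h1 = n1 = 0
    for s in seeds:
        cfg = null_config(SimConfig(seed=s, n_genes=n_genes, sigma_u=0.0,
                                    confounded_covariate="batch", confounding=0.5))
        cm, st, _ = generate(cfg)
        fcm, _ = q35_filter(cm)
        covs = select_covariates(fcm, st, seed=s + 1000).final_set
        sel = select_max_pcl(st)
        cm_sel = fcm.subset_samples(sel.sample_ids)
        de_raw = run_de(cm_sel, sel, "discrete", covariates=[])
        de_adj = run_de(cm_sel, sel, "discrete", covariates=covs)
        ok0, ok1 = de_raw["p"].notna(), de_adj["p"].notna()
        h0 += int((de_raw.loc[ok0, "p"] < 0.05).sum()); n0 += int(ok0.sum())
        h1 += int((de_adj.loc[ok1, "p"] < 0.05).sum()); n1 += int(ok1.sum())
    return {"unadjusted": h0 / n0, "adjusted": h1 / n1}


def recovery_config(seed: int, n_genes: int = 600) -> SimConfig:
    """Three detectable continuous confounders among 20 candidate covariates."""
    covs = [
        CovariateSim(f"conf{i + 1}", "continuous", n_affected=n_genes // 4, effect_sd=0.3)
        for i in range(3)
    ]
    return SimConfig(seed=seed, n_genes=n_genes, covariates=covs,
                     n_decoy_covariates=17, n_de_genes=0)


def covariate_recovery(n_runs: int = 50, base_seed: int = 300, n_genes: int = 600) -> dict:
    """Fraction of runs recovering all 3 planted confounders; mean decoys kept."""
    planted = {"conf1", "conf2", "conf3"}
    all_three = 0
    decoys = []
    for i in range(n_runs):
        cm, st, _ = generate(recovery_config(base_seed + i, n_genes))
        fcm, _ = q35_filter(cm)
        got = set(select_covariates(fcm, st, seed=base_seed + 1000 + i).final_set)
        all_three += int(planted <= got)
        decoys.append(len(got - planted))
    return {"all_planted_rate": all_three / n_runs, "mean_decoys": float(np.mean(decoys))}


def _glmm_inputs(seed: int, n_genes: int, sigma_u: float):
    cfg = SimConfig(seed=seed, n_genes=n_genes, sigma_u=sigma_u, covariates=[],
                    n_de_genes=0, baseline_log_mean=float(np.log(100)),
                    baseline_log_sd=0.3)
    cm, st, _ = generate(cfg)
    nf = tmm_factors(cm)
    X, _, tc, keep = build_design(st, [], "continuous")
    offset = np.log(nf.effective_lib[keep])
    subjects = st.data.loc[keep, "subject_id"].to_numpy()
    return cm, X, offset, subjects, tc


def glmm_sigma_zero_equivalence(seed: int = 700, n_genes: int = 50) -> dict:
    """|GLMM - GLM| trait coefficients on cohorts with no subject effect.

    The ML random-intercept SD on sigma_u = 0 data is half-normal around the
    boundary, so individual genes can legitimately land at sigma_hat > 0 with
    a slightly shifted coefficient; the mean absolute difference is the
    quantity the equivalence argument is about.
    """
    cm, X, offset, subjects, tc = _glmm_inputs(seed, n_genes, sigma_u=0.0)
    diffs = []
    for g in range(n_genes):
        glm = fit_nb(cm.counts[g].astype(float), X, offset)
        mm = fit_nb_glmm(cm.counts[g], X, offset, subjects, test_col=tc)
        diffs.append(abs(mm["coef"] - glm.beta[tc]))
    return {"mean_abs_diff": float(np.mean(diffs)), "max_abs_diff": float(np.max(diffs))}


def glmm_sigma_ladder(
    sigmas=(0.0, 0.25, 0.5, 1.0), genes_per_rung: int = 100, base_seed: int = 600
) -> list[float]:
    """Mean estimated random-intercept SD at each generative value."""
    means = []
    for j, s in enumerate(sigmas):
        cm, X, offset, subjects, tc = _glmm_inputs(base_seed + j, genes_per_rung, s)
        ests = [
            fit_nb_glmm(cm.counts[g], X, offset, subjects, test_col=tc)["sigma_u"]
            for g in range(genes_per_rung)
        ]
        means.append(float(np.mean(ests)))
    return means


def _pa_null_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, n_subjects=40, repeat_pattern=(40, 0, 0),
                     n_genes=200, covariates=[], sigma_u=0.0, n_de_genes=0)


def _pa_planted_config(seed: int) -> SimConfig:
    covs = [CovariateSim(f"f{i}", "continuous", n_affected=70, effect_sd=0.5)
            for i in range(3)]
    return SimConfig(seed=seed, n_subjects=40, repeat_pattern=(40, 0, 0),
                     n_genes=200, covariates=covs, sigma_u=0.0, n_de_genes=0)


def parallel_analysis_rates(n_runs: int = 50, base_seed: int = 400) -> dict:
    """Null k=0 rate and 3-factor k>=3 rate for permutation PC selection."""
    k_null = []
    k_planted = []
    for i in range(n_runs):
        cm, _, _ = generate(_pa_null_config(base_seed + i))
        k_null.append(select_num_pcs(cm, size_factors(cm), seed=base_seed + 1000 + i).k_selected)
        cm, _, _ = generate(_pa_planted_config(base_seed + 2000 + i))
        k_planted.append(select_num_pcs(cm, size_factors(cm), seed=base_seed + 3000 + i).k_selected)
    k_null, k_planted = np.array(k_null), np.array(k_planted)
    return {
        "null_k0_rate": float(np.mean(k_null == 0)),
        "planted_k3_rate": float(np.mean(k_planted >= 3)),
    }
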