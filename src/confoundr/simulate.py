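"""Synthetic post-deployment cohorts with known ground truth.

The generator emulates the study design the analysis assumes: 85 subjects of
whom 58 contribute one blood draw, 21 two and 6 three (118 measurements), a
PCL-M symptom score whose subject-level peak splits the cohort roughly 58
control / 27 symptoms at the >=34 dichotomy, an aggregate categorical batch,
continuous blood-count and sequencing-QC covariates with planted loadings on
gene expression, optional batch-trait confounding, trait-linked DE genes and
subject-level random intercepts. Counts are negative-binomial around a
log-linear mean with a library-size offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleTable, write_counts, write_sample_table

#: Table-1 style PCL-M mixture: control and symptoms group means/SDs.
_CONTROL_MEAN, _CONTROL_SD = 22.73, 4.46
_SYMPTOM_MEAN, _SYMPTOM_SD = 47.18, 10.31
_P_SYMPTOM = 27.0 / 85.0


@dataclass
class CovariateSim:
    """One simulated covariate: its distribution and its expression loadings.

    ``n_affected`` genes receive loadings ~ N(0, effect_sd) (per level for a
    categorical covariate); continuous covariates act through their
    standardized value. ``level`` is 'subject' (constant within subject) or
    'measurement' (redrawn per blood draw).
    """

    name: str
    ctype: str  # binary | continuous | categorical
    n_affected: int
    effect_sd: float
    n_levels: int = 4
    dist: str = "normal"  # normal | lognormal | logitnormal
    loc: float = 0.0
    scale: float = 1.0
    level: str = "measurement"


def default_covariates(n_genes: int) -> list[CovariateSim]:
    frac = max(1, n_genes // 5)
    return [
        CovariateSim("batch", "categorical", n_affected=n_genes, effect_sd=0.15,
                     n_levels=4, level="subject"),
        CovariateSim("neutrophil_count", "continuous", n_affected=frac, effect_sd=0.2,
                     dist="lognormal", loc=np.log(4.0), scale=0.35, level="subject"),
        CovariateSim("wbc_count", "continuous", n_affected=frac, effect_sd=0.2,
                     dist="lognormal", loc=np.log(6.8), scale=0.3, level="subject"),
        CovariateSim("gc_pct", "continuous", n_affected=frac, effect_sd=0.15,
                     dist="logitnormal", loc=-0.08, scale=0.15),
        CovariateSim("mapped_pct", "continuous", n_affected=frac, effect_sd=0.15,
                     dist="logitnormal", loc=2.2, scale=0.3),
        CovariateSim("nonexonic_pct", "continuous", n_affected=frac, effect_sd=0.15,
                     dist="logitnormal", loc=-1.1, scale=0.25),
        CovariateSim("dedup_pct", "continuous", n_affected=frac, effect_sd=0.15,
                     dist="logitnormal", loc=0.6, scale=0.3),
    ]


@dataclass
class SimConfig:
    n_subjects: int = 85
    repeat_pattern: tuple[int, int, int] = (58, 21, 6)  # subjects with 1/2/3 draws
    n_genes: int = 2000
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    lib_size_log_mean: float = float(np.log(2e7))
    lib_size_log_sd: float = 0.25
    covariates: list[CovariateSim] | None = None
    n_decoy_covariates: int = 0
    n_de_genes: int = 50
    de_log2fc: float = 1.0  # discrete-model effect on subject peak >= 34
    de_slope: float = 0.0  # per-PCL-M-unit log effect; used when de_mode='continuous'
    de_mode: str = "discrete"
    sigma_u: float = 0.5
    pcl_jitter_sd: float = 3.0
    confounded_covariate: str | None = None
    confounding: float = 0.0
    gene_length_log_mean: float = float(np.log(1500.0))
    gene_length_log_sd: float = 0.6
    seed: int = 1

    def validate(self) -> None:
        if sum(self.repeat_pattern) != self.n_subjects:
            raise ValueError("repeat_pattern must sum to n_subjects")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.sigma_u < 0 or self.dispersion < 0:
            raise ValueError("SDs and dispersion must be non-negative")
        if not 0.0 <= self.confounding <= 1.0:
            raise ValueError("confounding must lie in [0, 1]")


@dataclass
class SimTruth:
    de_genes: pd.DataFrame  # gene, true log-FC (natural log), mode
    loadings: dict[str, pd.DataFrame]  # covariate -> (gene, loading[, level])
    subject_intercepts: pd.DataFrame  # genes x subjects
    dispersion: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def null_config(base: SimConfig) -> SimConfig:
    """Copy of ``base`` with no trait-linked genes; confounders preserved."""
    return replace(base, n_de_genes=0)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_covariate(rng, spec: CovariateSim, n: int):
    if spec.ctype in ("categorical", "binary"):
        k = 2 if spec.ctype == "binary" else spec.n_levels
        return rng.integers(0, k, size=n)
    z = rng.normal(spec.loc, spec.scale, size=n)
    if spec.dist == "lognormal":
        return np.exp(z)
    if spec.dist == "logitnormal":
        return 100.0 / (1.0 + np.exp(-z))  # percentage support
    return z


def generate(config: SimConfig) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Draw one cohort. Deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    covs = list(config.covariates) if config.covariates is not None else default_covariates(config.n_genes)
    for i in range(config.n_decoy_covariates):
        covs.append(CovariateSim(f"decoy{i + 1:02d}", "continuous", 0, 0.0))

    # --- subjects and measurements -------------------------------------
    n_sub = config.n_subjects
    n_meas_per_sub = np.repeat([1, 2, 3], config.repeat_pattern)
    rng.shuffle(n_meas_per_sub)
    subject_ids = np.array([f"S{i + 1:03d}" for i in range(n_sub)])
    symptomatic = rng.random(n_sub) < _P_SYMPTOM
    peak = np.where(
        symptomatic,
        _truncnorm(rng, _SYMPTOM_MEAN, _SYMPTOM_SD, 34.0, 85.0, n_sub),
        _truncnorm(rng, _CONTROL_MEAN, _CONTROL_SD, 17.0, 33.99, n_sub),
    )

    rows = []
    for i in range(n_sub):
        m = n_meas_per_sub[i]
        peak_at = rng.integers(0, m)
        for k in range(m):
            if k == peak_at:
                score = peak[i]
            else:
                score = float(np.clip(peak[i] - abs(rng.normal(0, config.pcl_jitter_sd)), 17.0, peak[i]))
            rows.append((f"{subject_ids[i]}_m{k + 1}", subject_ids[i], k + 1, score, i))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "collection", "pcl_m", "_subj_idx"])
    n_meas = len(meta)
    subj_idx = meta["_subj_idx"].to_numpy()

    # --- covariates ------------------------------------------------------
    cov_values: dict[str, np.ndarray] = {}
    cov_types: dict[str, str] = {}
    z_pcl = (peak - peak.mean()) / max(peak.std(), 1e-12)
    for spec in covs:
        cov_types[spec.name] = spec.ctype
        n_draw = n_sub if spec.level == "subject" else n_meas
        vals = _draw_covariate(rng, spec, n_draw)
        if spec.name == config.confounded_covariate and config.confounding > 0:
            if spec.ctype in ("categorical", "binary"):
                if spec.level != "subject":
                    raise ValueError("categorical confounding requires a subject-level covariate")
                k = 2 if spec.ctype == "binary" else spec.n_levels
                # with probability `confounding`, the batch is determined by group
                forced = rng.random(n_sub) < config.confounding
                assigned = np.where(symptomatic, 0, 1 + rng.integers(0, k - 1, size=n_sub))
                vals = np.where(forced, assigned, vals)
            else:
                rho = config.confounding
                eps = rng.normal(size=n_sub)
                z = rho * z_pcl + np.sqrt(1 - rho**2) * eps
                base = spec.loc + spec.scale * z
                if spec.dist == "lognormal":
                    subj = np.exp(base)
                elif spec.dist == "logitnormal":
                    subj = 100.0 / (1.0 + np.exp(-base))
                else:
                    subj = base
                vals = subj if spec.level == "subject" else subj[subj_idx]
        if spec.level == "subject" and len(vals) == n_sub:
            vals = np.asarray(vals)[subj_idx]
        if spec.ctype in ("categorical", "binary"):
            vals = np.array([f"{spec.name[:1].upper()}{int(v)}" for v in vals])
        cov_values[spec.name] = np.asarray(vals)

    # --- gene-level parameters ------------------------------------------
    G = config.n_genes
    gene_ids = np.array([f"G{g + 1:05d}" for g in range(G)])
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G)
    alpha = np.full(G, config.dispersion)
    lengths = np.exp(rng.normal(config.gene_length_log_mean, config.gene_length_log_sd, size=G))
    lengths = np.maximum(lengths.astype(np.int64), 200)

    log_mu = np.tile(baseline[:, None], (1, n_meas))

    loadings: dict[str, pd.DataFrame] = {}
    for spec in covs:
        if spec.n_affected == 0 or spec.effect_sd == 0:
            continue
        affected = rng.choice(G, size=min(spec.n_affected, G), replace=False)
        if spec.ctype in ("categorical", "binary"):
            k = 2 if spec.ctype == "binary" else spec.n_levels
            # every level carries its own iid effect; only level contrasts
            # are identifiable, so no reference level is special-cased
            lam = rng.normal(0.0, spec.effect_sd, size=(len(affected), k))
            levels = sorted(pd.unique(cov_values[spec.name]))
            lev_index = pd.Series(cov_values[spec.name]).map(
                {lev: i for i, lev in enumerate(levels)}
            ).to_numpy()
            log_mu[affected] += lam[:, lev_index]
            loadings[spec.name] = pd.DataFrame(
                {
                    "gene": np.repeat(gene_ids[affected], k),
                    "level": np.tile(levels, len(affected)),
                    "loading": lam.ravel(),
                }
            )
        else:
            v = cov_values[spec.name].astype(float)
            z = (v - v.mean()) / max(v.std(), 1e-12)
            lam = rng.normal(0.0, spec.effect_sd, size=len(affected))
            log_mu[affected] += lam[:, None] * z[None, :]
            loadings[spec.name] = pd.DataFrame(
                {"gene": gene_ids[affected], "loading": lam}
            )

    # --- trait effect (enters through the subject's peak score) ---------
    de_rows = []
    if config.n_de_genes > 0:
        de_idx = rng.choice(G, size=config.n_de_genes, replace=False)
        signs = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
        if config.de_mode == "discrete":
            eff = signs * config.de_log2fc * np.log(2.0)
            trait_vec = symptomatic[subj_idx].astype(float)
        else:
            eff = signs * config.de_slope
            trait_vec = peak[subj_idx] - peak.mean()
        log_mu[de_idx] += eff[:, None] * trait_vec[None, :]
        de_rows = list(zip(gene_ids[de_idx], eff, [config.de_mode] * len(de_idx)))
    de_genes = pd.DataFrame(de_rows, columns=["gene", "log_fc", "mode"])

    # --- random intercepts and depth offset -----------------------------
    # gene-specific subject intercepts: a subject effect shared by all genes
    # would be indistinguishable from sequencing depth and absorbed by the
    # library-size offset, so the intercepts the mixed model estimates are
    # drawn independently per (gene, subject)
    intercepts = rng.normal(0.0, config.sigma_u, size=(G, n_sub))
    log_mu += intercepts[:, subj_idx]
    lib = np.exp(rng.normal(config.lib_size_log_mean, config.lib_size_log_sd, size=n_meas))
    log_mu += np.log(lib / np.exp(config.lib_size_log_mean))[None, :]

    mu = np.exp(np.clip(log_mu, -30, 30))
    if config.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    cm = CountMatrix(
        gene_ids=list(gene_ids),
        sample_ids=list(meta["sample_id"]),
        counts=counts.astype(np.int64),
        gene_lengths=lengths,
    )
    table = meta.drop(columns=["_subj_idx"]).copy()
    for name, vals in cov_values.items():
        table[name] = vals
    st = SampleTable(table, cov_types)
    truth = SimTruth(
        de_genes=de_genes,
        loadings=loadings,
        subject_intercepts=pd.DataFrame(intercepts, index=gene_ids, columns=subject_ids),
        dispersion=alpha,
        config=config,
    )
    return cm, st, truth


def write_cohort(cm: CountMatrix, st: SampleTable, truth: SimTruth, out_dir: str | Path) -> None:
    """Write counts.tsv, samples.tsv and truth.tsv in the canonical dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(cm, out / "counts.tsv")
    write_sample_table(st, out / "samples.tsv")
    parts = [truth.de_genes.assign(kind="de_gene")]
    for cov, df in truth.loadings.items():
        parts.append(df.assign(kind=f"loading:{cov}"))
    pd.concat(parts, ignore_index=True).to_csv(out / "truth.tsv", sep="\t", index=False, na_rep="NA")
    with open(out / "covariate_spec.tsv", "w") as fh:
        for name, ctype in st.covariate_types.items():
            fh.write(f"{name}\t{ctype}\n")
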