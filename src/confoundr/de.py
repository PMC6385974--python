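"""Per-gene differential expression on the PCL-M symptom score.

One measurement per subject (the highest-score one) is regressed gene by gene
with a negative-binomial log-linear model, with the trait coded either as the
continuous score or dichotomized into control (< 34) and symptoms (>= 34)
groups. Multiple testing is controlled genome-wide by Benjamini-Hochberg and,
optionally, within supplied prior gene sets ("restricted FDR").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import build_design
from .io import CountMatrix, GeneSet, SampleTable
from .nbglm import fit_nb_glm
from .normalize import NormFactors

logger = logging.getLogger(__name__)

#: PCL-M dichotomy: scores >= 34 define the symptoms group.
SYMPTOM_THRESHOLD = 34.0


def select_max_pcl(st: SampleTable) -> SampleTable:
    """Keep, per subject, the measurement with the highest PCL-M score.

    Ties are broken by earliest collection index (if a ``collection`` column
    is present), then by file order.
    """
    df = st.data.reset_index(drop=True)
    order = np.arange(len(df))
    key = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "pcl": -df["pcl_m"].to_numpy(),
            "collection": df["collection"] if "collection" in df else order,
            "order": order,
        }
    )
    best = (
        key.sort_values(["pcl", "collection", "order"], kind="stable")
        .groupby("subject_id", sort=False)
        .head(1)["order"]
        .to_numpy()
    )
    best.sort()
    return SampleTable(df.iloc[best].reset_index(drop=True), dict(st.covariate_types))


def dichotomize(st: SampleTable, threshold: float = SYMPTOM_THRESHOLD) -> pd.Series:
    """Label each measurement 'control' (< threshold) or 'symptoms' (>= threshold)."""
    return pd.Series(
        np.where(st.data["pcl_m"].to_numpy() >= threshold, "symptoms", "control"),
        index=st.data["sample_id"],
        name="group",
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate as NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def restricted_fdr(table: pd.DataFrame, gs: GeneSet) -> np.ndarray:
    """BH adjustment confined to the p-values of genes in ``gs``.

    Non-members get NaN. Raises if the set does not intersect the table.
    """
    member = table["gene"].isin(gs.members).to_numpy()
    if not member.any():
        raise ValueError(f"gene set {gs.name!r} has no genes in the result table")
    out = np.full(len(table), np.nan)
    out[member] = bh_fdr(table.loc[member, "p"].to_numpy())
    return out


def run_de(
    cm: CountMatrix,
    st: SampleTable,
    trait_mode: str,
    covariates: list[str] | None = None,
    gene_sets: list[GeneSet] | None = None,
    nf: NormFactors | None = None,
    threshold: float = SYMPTOM_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene NB regression of counts on the trait with fixed covariates.

    Offsets are log effective library sizes (raw depth x TMM factor).
    Returns one row per gene: coefficient (natural-log scale), fold-change,
    LRT p-value, dispersion, convergence flag, genome-wide BH-FDR and one
    restricted-FDR column per gene set.
    """
    from .normalize import tmm_factors

    covariates = covariates or []
    st = st.aligned_to(cm)
    if nf is None:
        nf = tmm_factors(cm)
    X, names, trait_col, keep = build_design(st, covariates, trait_mode, threshold)
    offset = np.log(nf.effective_lib[keep])
    counts = cm.counts[:, keep]
    trait_vals = X[:, trait_col]
    if len(np.unique(trait_vals)) < 2:
        raise ValueError("trait has fewer than two distinct values among retained rows")

    rows = []
    for g in range(cm.n_genes):
        try:
            res = fit_nb_glm(counts[g], X, offset, trait_col)
        except Exception:  # a pathological gene must not abort the run
            logger.exception("fit failed for gene %s", cm.gene_ids[g])
            rows.append((np.nan, np.nan, np.nan, False))
            continue
        rows.append((res.coef, res.p, res.dispersion, res.converged))
    coef, p, disp, conv = map(np.asarray, zip(*rows))
    p = np.where(np.asarray(conv, dtype=bool), p, np.nan)
    table = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "coef": coef,
            "fc": np.exp(coef),
            "log2fc": coef / np.log(2.0),
            "p": p,
            "dispersion": disp,
            "converged": np.asarray(conv, dtype=bool),
        }
    )
    table["fdr_all"] = bh_fdr(table["p"].to_numpy())
    for gs in gene_sets or []:
        table[f"fdr_{gs.name}"] = restricted_fdr(table, gs)
    return table


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (log2 fold-change, -log10 p) pairs for volcano plotting."""
    return pd.DataFrame(
        {
            "gene": de["gene"],
            "log2fc": de["log2fc"],
            "neg_log10_p": -np.log10(de["p"]),
        }
    )
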