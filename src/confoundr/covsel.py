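"""Selection of nuisance covariates driving global expression patterns.

The number of informative principal components is chosen by permutation
calibration (parallel analysis): eigenvalues of the normalized real matrix
are compared with eigenvalues from replicates in which every gene's raw
counts are independently permuted across samples and the normalization is
recomputed. Candidate covariates are screened per component with a test
matched to their type, confirmed by greedy stepwise regression with a nested
likelihood-ratio test, and finally pruned for mutual correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import CountMatrix, SampleTable
from .normalize import NormFactors, size_factors

logger = logging.getLogger(__name__)

SCREEN_P = 0.1
MODEL_P = 0.001
PRUNE_THRESHOLD = 0.8


def normalized_log_matrix(cm: CountMatrix, nf: NormFactors, log: bool = True) -> np.ndarray:
    """Samples x genes matrix of size-factor-normalized (optionally log2) counts.

    log2(x/sf + 1) keeps high-count genes from dominating the principal
    components; ``log=False`` gives the plain normalized counts.
    """
    if nf.size_factor is None:
        raise ValueError("median-of-ratios size factors required for PCA input")
    y = cm.counts / nf.size_factor[None, :]
    if log:
        y = np.log2(y + 1.0)
    return y.T


@dataclass
class PCResult:
    scores: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # per-component variance of the real data
    perm_eigenvalues: np.ndarray | None = None  # n_perm x rank
    k_selected: int | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_normalized(
    cm: CountMatrix,
    nf: NormFactors,
    n_components: int | None = None,
    log: bool = True,
) -> PCResult:
    """PCA of the normalized, log-transformed, gene-centered matrix.

    Samples are observations; eigenvalues are the per-component variances
    (sum equals the total per-gene variance of the transformed matrix).
    """
    if cm.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    Y = normalized_log_matrix(cm, nf, log=log)
    rank = min(Y.shape[0] - 1, Y.shape[1])
    k = rank if n_components is None else min(n_components, rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Y)
    return PCResult(scores=scores, eigenvalues=pca.explained_variance_.copy())


def _perm_eigenvalues(counts: np.ndarray, rng: np.random.Generator, log: bool) -> np.ndarray:
    perm = counts.copy()
    for g in range(perm.shape[0]):
        rng.shuffle(perm[g])
    cm_perm = CountMatrix(
        gene_ids=[f"g{i}" for i in range(perm.shape[0])],
        sample_ids=[f"s{j}" for j in range(perm.shape[1])],
        counts=perm,
    )
    nf_perm = size_factors(cm_perm)
    Y = normalized_log_matrix(cm_perm, nf_perm, log=log)
    pca = PCA(svd_solver="full")
    pca.fit(Y)
    return pca.explained_variance_


def select_num_pcs(
    cm: CountMatrix,
    nf: NormFactors,
    n_perm: int = 5,
    seed: int | np.random.Generator = 1,
    max_pcs: int = 10,
    log: bool = True,
) -> PCResult:
    """Choose the number of informative PCs by parallel analysis.

    Each permuted replicate shuffles every gene's raw counts independently
    across samples and is renormalized from scratch. ``k_selected`` is the
    largest k (capped at ``max_pcs``) such that every real eigenvalue up to
    rank k strictly exceeds the maximum of the corresponding permuted
    eigenvalues across replicates.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation replicate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    res = pca_normalized(cm, nf, log=log)
    rank = len(res.eigenvalues)
    perms = np.vstack(
        [_perm_eigenvalues(cm.counts, rng, log)[:rank] for _ in range(n_perm)]
    )
    thresh = perms.max(axis=0)
    k = 0
    for j in range(min(rank, max_pcs)):
        if res.eigenvalues[j] > thresh[j]:
            k = j + 1
        else:
            break
    res.perm_eigenvalues = perms
    res.k_selected = k
    return res


# ---------------------------------------------------------------------------
# covariate screening


def _screen_one(values: pd.Series, ctype: str, pc_scores: np.ndarray) -> tuple[str, float, float]:
    """Type-matched association test of one covariate against one PC."""
    ok = values.notna().to_numpy()
    v = values[ok]
    s = pc_scores[ok]
    if ctype == "continuous":
        vals = pd.to_numeric(v).to_numpy()
        if len(np.unique(vals)) < 2:
            raise ValueError("single level")
        rho, p = stats.spearmanr(vals, s)
        return "Spearman", float(rho), float(p)
    levels = pd.unique(v)
    groups = [s[(v == lev).to_numpy()] for lev in levels]
    if len(levels) < 2:
        raise ValueError("single level")
    if ctype == "binary":
        a, b = groups
        method = "exact" if (len(s) <= 50 and len(np.unique(s)) == len(s)) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return "MWW", float(res.statistic), float(res.pvalue)
    res = stats.f_oneway(*groups)
    return "ANOVA", float(res.statistic), float(res.pvalue)


def screen_covariates(
    pcs: PCResult,
    st: SampleTable,
    screen_p: float = SCREEN_P,
    include_trait: bool = True,
) -> pd.DataFrame:
    """Test every covariate against every informative PC.

    Binary covariates use a two-sided Mann-Whitney-Wilcoxon test (exact
    enumeration for <= 50 untied observations, normal approximation with tie
    correction otherwise), continuous ones a Spearman correlation test, and
    categorical ones one-way ANOVA. Rows with p < ``screen_p`` are flagged as
    candidates. The PCL-M trait itself is screened for reporting but marked
    ineligible for selection as a nuisance covariate.
    """
    k = pcs.k_selected if pcs.k_selected is not None else pcs.n_components
    if k < 1:
        return pd.DataFrame(
            columns=["covariate", "pc", "test", "stat", "p", "candidate", "eligible"]
        )
    rows = []
    items = [(name, st.covariate_types[name], True) for name in st.covariates]
    if include_trait:
        items.append(("pcl_m", "continuous", False))
    for name, ctype, eligible in items:
        values = st.data[name]
        for j in range(k):
            try:
                test, stat, p = _screen_one(values, ctype, pcs.scores[:, j])
            except ValueError:
                logger.warning("covariate %s skipped for PC%d (single level)", name, j + 1)
                continue
            rows.append((name, j + 1, test, stat, p, p < screen_p, eligible))
    return pd.DataFrame(
        rows, columns=["covariate", "pc", "test", "stat", "p", "candidate", "eligible"]
    )


# ---------------------------------------------------------------------------
# greedy stepwise confirmation


def _covariate_block(st: SampleTable, name: str, rows: np.ndarray) -> np.ndarray:
    ctype = st.covariate_types.get(name, "continuous")
    col = st.data.loc[rows, name]
    if ctype == "continuous":
        return pd.to_numeric(col).to_numpy(dtype=float)[:, None]
    levels = list(pd.unique(col.dropna()))
    return np.hstack([(col == lev).to_numpy(dtype=float)[:, None] for lev in levels[1:]]) if len(levels) > 1 else np.empty((rows.sum(), 0))


def _gaussian_loglik(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def greedy_stepdown(
    pcs: PCResult,
    st: SampleTable,
    screen_table: pd.DataFrame,
    model_p: float = MODEL_P,
) -> dict[int, list[str]]:
    """Stepwise confirmation of screened covariates, per principal component.

    For each PC the candidates (screen p < 0.1, eligible) are offered in
    order of ascending screen p-value to an incremental linear model of the
    PC scores; a candidate is kept iff the nested-model likelihood-ratio test
    (chi-square, df = columns added) falls below ``model_p``. Because a
    highly predictive covariate absorbs its correlates' signal, redundant
    candidates offered later fail the test and drop out.
    """
    order = {name: i for i, name in enumerate(st.covariates)}
    selected: dict[int, list[str]] = {}
    k = pcs.k_selected if pcs.k_selected is not None else pcs.n_components
    for j in range(1, k + 1):
        cand = screen_table[
            (screen_table["pc"] == j)
            & screen_table["candidate"]
            & screen_table["eligible"]
        ].copy()
        cand["file_order"] = cand["covariate"].map(order)
        cand = cand.sort_values(["p", "file_order"], kind="stable")
        kept: list[str] = []
        if cand.empty:
            selected[j] = kept
            continue
        names = list(cand["covariate"])
        rows = np.ones(len(st.data), dtype=bool)
        for name in names:
            rows &= st.data[name].notna().to_numpy()
        y = pcs.scores[rows, j - 1]
        X = np.ones((rows.sum(), 1))
        ll = _gaussian_loglik(y, X)
        for name in names:
            block = _covariate_block(st, name, rows)
            if block.shape[1] == 0:
                continue
            X_new = np.hstack([X, block])
            if np.linalg.matrix_rank(X_new) < X_new.shape[1]:
                logger.info("PC%d: %s rejected (rank-deficient design)", j, name)
                continue
            ll_new = _gaussian_loglik(y, X_new)
            stat = max(0.0, 2.0 * (ll_new - ll))
            p = stats.chi2.sf(stat, df=block.shape[1])
            if p < model_p:
                kept.append(name)
                X, ll = X_new, ll_new
        selected[j] = kept
    return selected


# ---------------------------------------------------------------------------
# correlation pruning


def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b)
    if min(tab.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))


def _eta(cont: pd.Series, cat: pd.Series) -> float:
    y = pd.to_numeric(cont).to_numpy(dtype=float)
    groups = [y[(cat == lev).to_numpy()] for lev in pd.unique(cat)]
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups if len(g))
    ss_total = float(((y - grand) ** 2).sum())
    return float(np.sqrt(ss_between / ss_total)) if ss_total > 0 else 0.0


def covariate_association(st: SampleTable, a: str, b: str) -> float:
    """Symmetric association in [0, 1]: |Spearman|, Cramér's V, or eta."""
    ta = st.covariate_types.get(a, "continuous")
    tb = st.covariate_types.get(b, "continuous")
    ok = st.data[a].notna().to_numpy() & st.data[b].notna().to_numpy()
    va, vb = st.data.loc[ok, a], st.data.loc[ok, b]
    if ta == "continuous" and tb == "continuous":
        rho = stats.spearmanr(pd.to_numeric(va), pd.to_numeric(vb))[0]
        return float(abs(rho))
    if ta != "continuous" and tb != "continuous":
        return _cramers_v(va, vb)
    return _eta(va, vb) if ta == "continuous" else _eta(vb, va)


def prune_correlated(
    per_pc_selected: dict[int, list[str]],
    st: SampleTable,
    screen_table: pd.DataFrame,
    threshold: float = PRUNE_THRESHOLD,
) -> list[str]:
    """Greedy pruning of mutually redundant covariates.

    Covariates are visited in order of their best screen p-value; one is
    dropped if its association with an already-retained covariate exceeds
    ``threshold``.
    """
    union = sorted({c for sel in per_pc_selected.values() for c in sel})
    if not union:
        return []
    best_p = (
        screen_table[screen_table["covariate"].isin(union)]
        .groupby("covariate")["p"]
        .min()
    )
    order = {name: i for i, name in enumerate(st.covariates)}
    ranked = sorted(union, key=lambda c: (best_p.get(c, 1.0), order.get(c, 0)))
    final: list[str] = []
    for c in ranked:
        if all(covariate_association(st, c, kept) <= threshold for kept in final):
            final.append(c)
        else:
            logger.info("pruned %s (correlated with retained covariate)", c)
    return final


@dataclass
class CovSelResult:
    pcs: PCResult
    screen_table: pd.DataFrame
    per_pc_selected: dict[int, list[str]] = field(default_factory=dict)
    final_set: list[str] = field(default_factory=list)


def select_covariates(
    cm: CountMatrix,
    st: SampleTable,
    n_perm: int = 5,
    seed: int = 1,
    max_pcs: int = 10,
    screen_p: float = SCREEN_P,
    model_p: float = MODEL_P,
    prune_threshold: float = PRUNE_THRESHOLD,
    log: bool = True,
) -> CovSelResult:
    """Full covariate-selection pass over a filtered count matrix."""
    st = st.aligned_to(cm)
    nf = size_factors(cm)
    pcs = select_num_pcs(cm, nf, n_perm=n_perm, seed=seed, max_pcs=max_pcs, log=log)
    screen = screen_covariates(pcs, st, screen_p=screen_p)
    per_pc = greedy_stepdown(pcs, st, screen, model_p=model_p)
    final = prune_correlated(per_pc, st, screen, threshold=prune_threshold)
    return CovSelResult(pcs=pcs, screen_table=screen, per_pc_selected=per_pc, final_set=final)
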