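"""Low-expression filtering and between-sample normalization.

Implements the q35 low-count filter (discard genes whose 75th-percentile raw
count falls below the 35% quantile of all genes' 75th percentiles), TMM
normalization factors, DESeq-style median-of-ratios size factors and RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountMatrix


@dataclass
class FilterReport:
    per_gene_p75: np.ndarray
    q35: float
    keep_mask: np.ndarray
    n_before: int
    n_after: int


def q35_filter(cm: CountMatrix, quantile: float = 0.35) -> tuple[CountMatrix, FilterReport]:
    """Discard genes whose 75th-percentile raw count is strictly below q35.

    Both quantiles use linear interpolation between order statistics (R's
    default quantile type 7). The boundary is strict: a gene exactly at q35
    is kept.
    """
    if cm.n_genes == 0 or cm.n_samples == 0:
        raise ValueError("cannot filter an empty count matrix")
    p75 = np.quantile(cm.counts, 0.75, axis=1, method="linear")
    q35 = float(np.quantile(p75, quantile, method="linear"))
    keep = p75 >= q35
    if not keep.any():
        raise ValueError(f"q35 filter removed every gene (q35={q35:g}); degenerate threshold")
    report = FilterReport(
        per_gene_p75=p75,
        q35=q35,
        keep_mask=keep,
        n_before=cm.n_genes,
        n_after=int(keep.sum()),
    )
    return cm.subset_genes(keep), report


@dataclass
class NormFactors:
    """Per-sample normalization factors.

    ``tmm`` factors multiply library sizes into effective library sizes;
    ``size_factor`` are median-of-ratios factors that divide counts directly.
    Either may be None if not computed.
    """

    sample_ids: list[str]
    lib_size: np.ndarray
    tmm: np.ndarray | None = None
    size_factor: np.ndarray | None = None

    @property
    def effective_lib(self) -> np.ndarray:
        if self.tmm is None:
            raise ValueError("TMM factors not computed")
        return self.lib_size * self.tmm


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed weighted mean of M-values for one sample against the reference.

    Genes with a zero in either sample drop out (log-ratio undefined); the
    middle (1 - 2*logratio_trim) of M-values and (1 - 2*sum_trim) of A-values
    are kept; weights are inverse asymptotic binomial variances.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(cm: CountMatrix) -> NormFactors:
    """TMM normalization factors, rescaled to geometric mean one.

    The reference sample is the one whose 75th-percentile of depth-scaled
    counts is closest to the mean across samples.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.library_sizes.astype(float)
    if (lib == 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero library size")
    x = cm.counts.astype(float)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(cm.n_samples)])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(cm.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(list(cm.sample_ids), lib, tmm=factors)


def size_factors(cm: CountMatrix) -> NormFactors:
    """DESeq median-of-ratios size factors.

    Each sample's factor is the median, over genes expressed in every sample,
    of the ratio of its count to the gene's geometric-mean pseudo-reference.
    """
    x = cm.counts.astype(float)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has nonzero counts in every sample; size factors undefined")
    log_geo = np.mean(np.log(x[pos]), axis=1, keepdims=True)
    ratios = np.log(x[pos]) - log_geo
    sf = np.exp(np.median(ratios, axis=0))
    return NormFactors(list(cm.sample_ids), cm.library_sizes.astype(float), size_factor=sf)


def rpkm(cm: CountMatrix, nf: NormFactors) -> np.ndarray:
    """Reads per kilobase per million effectively mapped reads.

    RPKM[g, s] = count / (length_g / 1e3) / (effective_lib_s / 1e6), where the
    effective library size is the raw depth scaled by the TMM factor.
    """
    if cm.gene_lengths is None:
        raise ValueError("RPKM requires gene lengths")
    eff = nf.effective_lib
    kb = cm.gene_lengths.astype(float) / 1e3
    return cm.counts / kb[:, None] / (eff[None, :] / 1e6)
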