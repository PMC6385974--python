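"""Design-matrix construction shared by the fixed-effect and mixed models."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import SampleTable

logger = logging.getLogger(__name__)


def encode_covariates(
    st: SampleTable, covariates: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Encode selected covariates as a numeric block.

    Continuous/binary-numeric columns enter as-is; categorical (and
    non-numeric binary) columns enter as full dummy blocks with the first
    observed level dropped. Rows with a missing value in any selected
    covariate are excluded and their count logged.

    Returns (matrix, column names, boolean row mask of retained measurements).
    """
    df = st.data
    keep = np.ones(len(df), dtype=bool)
    for name in covariates:
        keep &= df[name].notna().to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d measurements with missing covariate values", dropped)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    sub = df.loc[keep]
    for name in covariates:
        ctype = st.covariate_types.get(name, "continuous")
        col = sub[name]
        if ctype == "continuous":
            blocks.append(pd.to_numeric(col).to_numpy(dtype=float)[:, None])
            names.append(name)
        else:
            levels = list(pd.unique(col))
            for lev in levels[1:]:
                blocks.append((col == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{name}[{lev}]")
    if blocks:
        M = np.hstack(blocks)
    else:
        M = np.empty((keep.sum(), 0))
    return M, names, keep


def build_design(
    st: SampleTable,
    covariates: list[str],
    trait_mode: str = "continuous",
    threshold: float = 34.0,
) -> tuple[np.ndarray, list[str], int, np.ndarray]:
    """Intercept + trait + covariates design for per-gene regression.

    ``trait_mode='continuous'`` uses the raw PCL-M score; ``'discrete'`` uses
    the symptoms indicator (score >= threshold). Returns
    (X, column names, trait column index, retained-row mask).
    """
    cov_block, cov_names, keep = encode_covariates(st, covariates)
    pcl = st.data.loc[keep, "pcl_m"].to_numpy(dtype=float)
    if trait_mode == "continuous":
        trait = pcl
    elif trait_mode == "discrete":
        trait = (pcl >= threshold).astype(float)
    else:
        raise ValueError(f"unknown trait_mode {trait_mode!r}")
    n = keep.sum()
    X = np.hstack([np.ones((n, 1)), trait[:, None], cov_block])
    names = ["intercept", "trait"] + cov_names
    # guard against rank deficiency introduced by covariate collinearity
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient for the selected covariates")
    return X, names, 1, keep
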