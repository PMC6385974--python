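import numpy as np
import pytest

from confoundr import CountMatrix, SampleTable, SimConfig, generate

STUDY_COVARIATES = [
    "batch", "neutrophil_count", "wbc_count", "gc_pct",
    "mapped_pct", "nonexonic_pct", "dedup_pct",
]


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene default-design cohort shared by read-only tests."""
    cfg = SimConfig(seed=1234, n_genes=300, n_de_genes=15)
    return generate(cfg)


@pytest.fixture
def tiny_counts():
    counts = np.array([[10, 20], [0, 5], [7, 7]])
    return CountMatrix(["g1", "g2", "g3"], ["s1", "s2"], counts)


def make_sample_table(pcl, subjects=None, covariates=None, types=None, collection=None):
    import pandas as pd

    n = len(pcl)
    df = pd.DataFrame(
        {
            "sample_id": [f"m{i}" for i in range(n)],
            "subject_id": subjects or [f"S{i}" for i in range(n)],
            "pcl_m": pcl,
        }
    )
    if collection is not None:
        df["collection"] = collection
    for k, v in (covariates or {}).items():
        df[k] = v
    return SampleTable(df, types or {})
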