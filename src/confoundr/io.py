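"""Readers and writers for counts, sample metadata, gene sets and results.

All on-disk tables are tab-delimited UTF-8 text with a header row; missing
values are written as ``NA``. Gene and sample identifiers are opaque strings
matched exactly (case-sensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Inclusive bounds of the PCL-M symptom checklist (17 items, 1-5 each).
PCLM_MIN = 17.0
PCLM_MAX = 85.0

COVARIATE_TYPES = ("binary", "continuous", "categorical")


class ValidationError(ValueError):
    """An on-disk artifact violated a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw, non-negative integer read counts.

    ``gene_lengths`` (base pairs, aligned to ``gene_ids``) are optional and
    only needed for RPKM computation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts, np.round(self.counts)):
                    bad = np.argwhere(self.counts != np.round(self.counts))[0]
                    raise ValidationError(
                        f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                        f"sample {self.sample_ids[bad[1]]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
            if (self.counts < 0).any():
                bad = np.argwhere(self.counts < 0)[0]
                raise ValidationError(
                    f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths)
            if len(self.gene_lengths) != len(self.gene_ids):
                raise ValidationError("gene_lengths not aligned to gene_ids")
            if (self.gene_lengths <= 0).any():
                raise ValidationError("gene lengths must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        """Row subset preserving original gene order."""
        mask = np.asarray(mask_or_ids)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array(sorted(pos[g] for g in mask_or_ids), dtype=int)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx],
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            gene_lengths=self.gene_lengths,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """One row per measurement: subject, PCL-M score and typed covariates.

    ``data`` holds columns ``sample_id``, ``subject_id``, ``pcl_m`` plus one
    column per covariate; ``covariate_types`` maps covariate name to one of
    ``binary``, ``continuous``, ``categorical``. An optional ``collection``
    column (integer collection index per subject) breaks ties when selecting
    the highest-score measurement.
    """

    data: pd.DataFrame
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("sample_id", "subject_id", "pcl_m"):
            if col not in self.data.columns:
                raise ValidationError(f"sample table missing required column {col!r}")
        _check_unique(list(self.data["sample_id"]), "sample ID")
        pcl = pd.to_numeric(self.data["pcl_m"], errors="raise")
        if ((pcl < PCLM_MIN) | (pcl > PCLM_MAX)).any():
            bad = self.data.loc[(pcl < PCLM_MIN) | (pcl > PCLM_MAX), "sample_id"].iloc[0]
            raise ValidationError(
                f"pcl_m out of range [{PCLM_MIN:g}, {PCLM_MAX:g}] for sample {bad!r}"
            )
        self.data = self.data.copy()
        self.data["pcl_m"] = pcl.astype(float)
        for name, ctype in self.covariate_types.items():
            if ctype not in COVARIATE_TYPES:
                raise ValidationError(f"unknown covariate type {ctype!r} for {name!r}")
            if name not in self.data.columns:
                raise ValidationError(f"declared covariate {name!r} missing from table")
            col = self.data[name]
            if ctype == "continuous":
                self.data[name] = pd.to_numeric(col, errors="raise")
            else:
                vals = col.dropna().unique()
                if ctype == "binary" and len(vals) > 2:
                    raise ValidationError(
                        f"covariate {name!r} declared binary but has "
                        f"{len(vals)} distinct values"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_types)

    def aligned_to(self, cm: CountMatrix) -> "SampleTable":
        """Reorder rows to the count-matrix sample order; all must be present."""
        missing = set(self.sample_ids) - set(cm.sample_ids)
        extra = set(cm.sample_ids) - set(self.sample_ids)
        if extra:
            raise ValidationError(f"samples missing from table: {sorted(extra)[:5]}")
        df = self.data.set_index("sample_id").loc[cm.sample_ids].reset_index()
        if missing:
            logger.warning("dropping %d table rows with no count column", len(missing))
        return SampleTable(df, dict(self.covariate_types))


@dataclass
class GeneSet:
    """A named set of gene identifiers (exact string matching)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def read_counts(path: str | Path, with_lengths: bool = False) -> CountMatrix:
    """Read a gene x sample TSV (first column gene IDs, header of sample IDs).

    A ``length`` column is consumed as gene lengths (base pairs) rather than
    a sample; ``with_lengths=True`` makes its absence an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need at least one gene-ID and one sample column")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    lengths = None
    body = df.drop(columns=[gene_col])
    if with_lengths and "length" not in body.columns:
        raise ValidationError(f"{path}: no 'length' column")
    if "length" in body.columns:
        lengths = pd.to_numeric(body.pop("length")).to_numpy()
    sample_ids = list(body.columns)
    try:
        counts = body.apply(pd.to_numeric).to_numpy()
    except ValueError as e:
        raise ValidationError(f"{path}: non-numeric count cell ({e})") from None
    frac = counts != np.floor(counts)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValidationError(
            f"{path}: non-integer count at row {gene_ids[i]!r}, column {sample_ids[j]!r}"
        )
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {gene_ids[i]!r}, column {sample_ids[j]!r}"
        )
    return CountMatrix(gene_ids, sample_ids, counts.astype(np.int64), lengths)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame()
    df.index.name = "gene"
    if cm.gene_lengths is not None:
        df.insert(0, "length", cm.gene_lengths)
    df.to_csv(path, sep="\t")


def read_sample_table(
    path: str | Path,
    covariate_spec: Sequence[tuple[str, str]] | Mapping[str, str] = (),
) -> SampleTable:
    """Read the per-measurement metadata TSV; ``NA`` cells become missing."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, na_values=["NA"], keep_default_na=False)
    if isinstance(covariate_spec, Mapping):
        types = dict(covariate_spec)
    else:
        types = dict(covariate_spec)
    if "collection" in df.columns:
        df["collection"] = pd.to_numeric(df["collection"])
    return SampleTable(df, types)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_covariate_spec(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``name<TAB>type`` declaring covariate types."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "type"], dtype=str)
    return dict(zip(df["name"], df["type"]))


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from a GMT line or a one-ID-per-line file.

    A line containing tabs is treated as GMT (name, description, members);
    otherwise every non-blank line is a member and the set is named after the
    file stem. Duplicate IDs are collapsed with a warning.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValidationError(f"{path}: empty gene-set file")
    first = text.splitlines()[0]
    if "\t" in first:
        fields = first.split("\t")
        set_name, ids = fields[0], fields[2:]
    else:
        set_name = name or path.stem
        ids = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(ids) != len(set(ids)):
        logger.warning("gene set %s: %d duplicate IDs collapsed", set_name, len(ids) - len(set(ids)))
    return GeneSet(name or set_name, frozenset(ids))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gs.members)) + "\n")


# 12 significant digits keeps round-trips below 1-ulp drift for float64 used here.
_FLOAT_FMT = "%.12g"


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-expression result table as TSV.

    Column order is preserved as given (gene first); reals are formatted at 12
    significant digits so a read-back reproduces them to that precision.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
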