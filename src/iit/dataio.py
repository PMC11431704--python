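"""Readers and writers for every table the pipeline touches.

All files are tab-separated UTF-8 with a header row.  Gene identifiers are
opaque strings; no symbol mapping is attempted.  Readers validate eagerly and
raise :class:`ValueError` naming the offending row/column rather than
silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PHENOTYPES = ("cancer", "autoimmune", "healthy")

#: Column order of the results table written by :func:`write_results`.
RESULT_COLUMNS = [
    "gene_id",
    "log2fc_autoimmune",
    "fdr_autoimmune",
    "log2fc_cancer",
    "fdr_cancer",
    "w_autoimmune",
    "w_cancer",
    "z_autoimmune",
    "z_cancer",
    "intermediate",
    "ratio",
    "iit_score",
    "quadrant",
    "p_raw",
    "p_bonferroni",
    "freq_count",
    "freq_gated",
    "significant",
]


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.sample_ids))
        df.insert(0, "gene_id", list(self.gene_ids))
        return df

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to a boolean or index gene mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            tuple(self.gene_ids[i] for i in idx),
            self.sample_ids,
            self.counts[idx],
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample phenotype labels with optional study of origin."""

    sample_ids: tuple[str, ...]
    phenotypes: tuple[str, ...]
    study_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.phenotypes) != len(self.sample_ids):
            raise ValueError("phenotypes and sample_ids differ in length")
        if self.study_ids is not None and len(self.study_ids) != len(self.sample_ids):
            raise ValueError("study_ids and sample_ids differ in length")
        _check_unique(self.sample_ids, "sample")
        for sid, ph in zip(self.sample_ids, self.phenotypes):
            if ph not in PHENOTYPES:
                raise ValueError(
                    f"sample {sid!r} has phenotype {ph!r}; "
                    f"allowed values are {PHENOTYPES}"
                )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def mask(self, phenotype: str) -> np.ndarray:
        return np.array([p == phenotype for p in self.phenotypes])

    def count(self, phenotype: str) -> int:
        return int(self.mask(phenotype).sum())

    def with_phenotypes(self, phenotypes: Iterable[str]) -> "SampleTable":
        return SampleTable(self.sample_ids, tuple(phenotypes), self.study_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "phenotype": self.phenotypes}
        )
        if self.study_ids is not None:
            df["study_id"] = self.study_ids
        return df


@dataclass(frozen=True)
class DEGTable:
    """One disease-vs-healthy differential-expression result."""

    gene_ids: tuple[str, ...]
    log2fc: np.ndarray
    pvalue: np.ndarray
    fdr: np.ndarray
    comparison_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if n == 0:
            raise ValueError("no genes in DEG table")
        for name in ("log2fc", "pvalue", "fdr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per gene")
            object.__setattr__(self, name, arr)
        _check_unique(self.gene_ids, "gene")
        for name in ("pvalue", "fdr"):
            arr = getattr(self, name)
            bad = np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"{name} outside [0, 1] for gene {self.gene_ids[bad[0]]!r}: "
                    f"{arr[bad[0]]}"
                )

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2fc": self.log2fc,
                "pvalue": self.pvalue,
                "fdr": self.fdr,
            }
        )

    def subset(self, gene_ids: Iterable[str]) -> "DEGTable":
        """Restrict to the given genes, preserving the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return DEGTable(
            tuple(gene_ids),
            self.log2fc[idx],
            self.pvalue[idx],
            self.fdr[idx],
            self.comparison_label,
        )


@dataclass(frozen=True)
class KnownTargetTable:
    """Genes with an approved or in-development drug for one disease."""

    disease_label: str
    gene_ids: frozenset[str] = field(default_factory=frozenset)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV.

    The first column holds gene identifiers; the header row holds sample
    identifiers.  Cells must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need a gene_id column and at least 2 samples")
    gene_col = df.columns[0]
    gene_ids = tuple(df[gene_col].astype(str))
    sample_ids = tuple(str(c) for c in df.columns[1:])
    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        col = pd.to_numeric(df.iloc[:, j + 1], errors="coerce")
        bad = np.flatnonzero(col.isna() | (col % 1 != 0) | (col < 0))
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"{path}: invalid count {df.iloc[i, j + 1]!r} for gene "
                f"{gene_ids[i]!r}, sample {s!r} (non-negative integer required)"
            )
        counts[:, j] = col.astype(np.int64)
    return CountMatrix(gene_ids, sample_ids, counts)


def write_counts(path: str | Path, m: CountMatrix) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleTable:
    """Read sample metadata (sample_id, phenotype, optional study_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    study = tuple(df["study_id"].astype(str)) if "study_id" in df.columns else None
    return SampleTable(
        tuple(df["sample_id"].astype(str)),
        tuple(df["phenotype"].astype(str)),
        study,
    )


def write_metadata(path: str | Path, s: SampleTable) -> None:
    s.to_frame().to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path, label: str = "") -> DEGTable:
    """Read an externally produced differential-expression table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "pvalue", "fdr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no genes")
    try:
        return DEGTable(
            tuple(df["gene_id"].astype(str)),
            df["log2fc"].to_numpy(dtype=float),
            df["pvalue"].to_numpy(dtype=float),
            df["fdr"].to_numpy(dtype=float),
            label,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_deg_table(path: str | Path, t: DEGTable) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_known_targets(path: str | Path) -> dict[str, KnownTargetTable]:
    """Read a known-drug-target table (disease_label, gene_id pairs)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("disease_label", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.duplicated(["disease_label", "gene_id"]).any():
        dup = df[df.duplicated(["disease_label", "gene_id"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (disease, gene) pair "
            f"({dup['disease_label']!r}, {dup['gene_id']!r})"
        )
    out: dict[str, KnownTargetTable] = {}
    for label, grp in df.groupby("disease_label", sort=False):
        out[str(label)] = KnownTargetTable(
            str(label), frozenset(grp["gene_id"].astype(str))
        )
    return out


def write_results(path: str | Path, records: pd.DataFrame) -> None:
    """Write the per-gene results table with the fixed column schema.

    Floats are rendered with 9 significant digits so read/write round-trips
    are lossless well past 6 significant figures.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    missing = [c for c in RESULT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    records[RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.9g", na_rep=""
    )


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns: {missing}")
    return df
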