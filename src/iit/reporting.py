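"""Quadrant summaries, PCA quality control, and known-drug-target annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import CountMatrix, KnownTargetTable, SampleTable
from .scoring import QUADRANTS


def summarize_quadrants(records: pd.DataFrame) -> dict[str, int]:
    """Gene count per quadrant (I-IV plus the sign-degenerate "none")."""
    counts = records["quadrant"].value_counts() if len(records) else {}
    return {q: int(counts.get(q, 0)) for q in (*QUADRANTS, "none")}


def annotate_known_targets(
    sig_records: pd.DataFrame,
    known: dict[str, KnownTargetTable],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross the significant genes against locally supplied known-drug-target
    tables (one per disease).

    Returns annotations sorted by descending score, and summary counts:
    per disease ``known_<d>`` / ``novel_<d>`` plus ``shared_known`` (genes
    known for every disease provided).  Known + novel always sums to the
    number of significant genes for each disease.
    """
    diseases = list(known)
    rows = []
    for _, rec in sig_records.iterrows():
        g = rec["gene_id"]
        known_for = sorted(d for d in diseases if g in known[d].gene_ids)
        novel_for = sorted(d for d in diseases if g not in known[d].gene_ids)
        rows.append(
            {
                "gene_id": g,
                "iit_score": rec["iit_score"],
                "in_iit_significant": True,
                "known_for": ";".join(known_for),
                "novel_for": ";".join(novel_for),
                "shared_known": len(known_for) == len(diseases) > 0,
            }
        )
    ann = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "iit_score",
            "in_iit_significant",
            "known_for",
            "novel_for",
            "shared_known",
        ],
    )
    ann = ann.sort_values("iit_score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    summary: dict[str, int] = {"n_significant": len(ann)}
    for d in diseases:
        n_known = int(sum(1 for ks in ann["known_for"] for k in [ks.split(";")] if d in k))
        summary[f"known_{d}"] = n_known
        summary[f"novel_{d}"] = len(ann) - n_known
    summary["shared_known"] = int(ann["shared_known"].sum()) if len(ann) else 0
    return ann, summary


def pca_qc(
    m: CountMatrix, s: SampleTable, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA on per-gene z-normalized counts.

    Counts are z-normalized per gene across samples (so high-count genes do
    not dominate); constant genes are dropped.  Samples are projected onto
    the top right singular directions of the gene x sample matrix.  Signs
    are fixed by making each component's largest-magnitude gene loading
    positive, so coordinates are bit-reproducible.

    Returns (coordinates DataFrame with sample_id/phenotype/PC columns,
    explained-variance fractions).
    """
    if len(m.sample_ids) < 3:
        raise ValueError("need at least 3 samples for PCA")
    x = m.counts.astype(float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes constant; nothing to decompose")
    x = x[keep]
    x = (x - x.mean(axis=1, keepdims=True)) / sd[keep, None]
    u, svals, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(svals))
    for comp in range(k):
        i = int(np.argmax(np.abs(u[:, comp])))
        if u[i, comp] < 0:
            u[:, comp] *= -1
            vt[comp] *= -1
    coords = (svals[:k, None] * vt[:k]).T  # samples x components
    df = pd.DataFrame(
        {"sample_id": m.sample_ids, "phenotype": s.phenotypes}
    )
    for comp in range(k):
        df[f"PC{comp + 1}"] = coords[:, comp]
    total = float((svals**2).sum())
    return df, (svals[:k] ** 2) / total
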