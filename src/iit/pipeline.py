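"""End-to-end orchestration: filter, differential expression, scoring,
permutation null, significance, frequency gate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .dataio import CountMatrix, DEGTable, SampleTable
from .diffexpr import DEConfig, differential_expression, filter_low_expression
from .permutation import (
    bonferroni,
    build_null,
    finalize_significance,
    frequency_counts,
    frequency_gate,
    pooled_pvalues,
)
from .scoring import run_iit


@dataclass
class PipelineResult:
    records: pd.DataFrame
    overlap_pool: set[str]
    summary: dict[str, Any] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_pipeline(
    m: CountMatrix,
    s: SampleTable,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    freq_alpha: float = 0.05,
    sig_threshold: float = 0.05,
    p_method: str = "normal",
    de_config: DEConfig | None = None,
    deg_a: DEGTable | None = None,
    deg_c: DEGTable | None = None,
) -> PipelineResult:
    """Run the full analysis on a count matrix and sample metadata.

    If external DEG tables are supplied (``deg_a``/``deg_c``), they replace
    the internal engine for the original comparison; the permutation null
    always uses the internal engine.  The scored universe for the original
    comparison is the genes shared by the two DEG tables; p-values for genes
    outside the null universe use their position in the same pooled
    distribution.
    """
    cfg = de_config or DEConfig()
    log: list[str] = [
        f"seed={seed} n_perm={n_perm} alpha={alpha} freq_alpha={freq_alpha} "
        f"sig_threshold={sig_threshold} p_method={p_method}",
        f"de_config: min_count={cfg.min_count} min_samples={cfg.min_samples} "
        f"prior_count={cfg.prior_count} variance_floor={cfg.variance_floor}",
    ]
    if tuple(s.sample_ids) != tuple(m.sample_ids):
        raise ValueError("metadata samples do not match count matrix samples")

    smallest = min(s.count(p) for p in ("cancer", "autoimmune", "healthy"))
    n_before = len(m.gene_ids)
    m = filter_low_expression(m, cfg, smallest_group=smallest)
    log.append(
        f"expression filter: {n_before} -> {len(m.gene_ids)} genes "
        f"(min_count={cfg.min_count}, min_samples="
        f"{cfg.min_samples if cfg.min_samples is not None else smallest})"
    )

    external = deg_a is not None or deg_c is not None
    if external and (deg_a is None or deg_c is None):
        raise ValueError("supply both external DEG tables or neither")
    if not external:
        deg_a = differential_expression(m, s, "autoimmune", cfg)
        deg_c = differential_expression(m, s, "cancer", cfg)
        log.append("original comparison: internal DE engine")
    else:
        log.append(
            "original comparison: external DEG tables; the permutation null "
            "uses the internal engine"
        )

    records, pool = run_iit(deg_a, deg_c, sig_threshold)
    log.append(
        f"shared gene universe: {len(records)}; overlap pool "
        f"(FDR < {sig_threshold} in both): {len(pool)}"
    )

    null = build_null(m, s, n_perm, seed, cfg)
    log.append(
        f"null distribution: {null.size} permuted scores "
        f"({len(null.gene_ids)} genes x {n_perm} replicates)"
    )

    orig_scores = records["iit_score"].to_numpy()
    p_raw = pooled_pvalues(orig_scores, null, method=p_method)

    counts_all = frequency_counts(null, orig_scores, threshold=alpha, method=p_method)
    null_index = {g: i for i, g in enumerate(null.gene_ids)}
    idx = np.array([null_index.get(g, -1) for g in records["gene_id"]])
    n_outside = int((idx < 0).sum())
    if n_outside:
        log.append(
            f"warning: {n_outside} scored genes are absent from the null "
            f"universe (external DEG tables vs filtered counts); their "
            f"frequency counts are 0"
        )
    freq_count = np.where(idx >= 0, counts_all[np.maximum(idx, 0)], 0)

    # The gate's z-normalization population is the pre-gate significant set:
    # counts are compared among genes asserted significant, and outliers
    # (batch-noise behavior) are removed from that set.
    p_bonf = bonferroni(p_raw, max(len(pool), 1))
    genes = records["gene_id"].to_numpy()
    pre_sig = np.array([g in pool for g in genes]) & (p_bonf < alpha)
    sig_genes = tuple(genes[pre_sig])
    if pre_sig.sum() >= 2:
        gated, freq_p_sig = frequency_gate(
            sig_genes, freq_count[pre_sig], freq_alpha
        )
        freq_p = np.ones(len(records))
        freq_p[pre_sig] = freq_p_sig
    else:
        gated, freq_p = set(), np.ones(len(records))
    mean_sig_count = float(freq_count[pre_sig].mean()) if pre_sig.any() else 0.0
    log.append(
        f"frequency counts: mean {counts_all.mean():.2f} of {n_perm} over all "
        f"genes, {mean_sig_count:.2f} over the significant set; gated genes: "
        f"{len(gated)}"
    )

    final = finalize_significance(
        records, pool, p_raw, freq_count, freq_p, gated, alpha
    )
    n_sig_pre = int(pre_sig.sum())
    n_sig = int(final["significant"].sum())
    log.append(
        f"significant before gate: {n_sig_pre}; removed by gate: "
        f"{len(gated)}; final significant: {n_sig}"
    )
    summary = {
        "genes_input": n_before,
        "genes_filtered": len(m.gene_ids),
        "genes_shared": len(records),
        "overlap_pool": len(pool),
        "null_scores": null.size,
        "mean_freq_count": float(counts_all.mean()),
        "mean_freq_count_significant": mean_sig_count,
        "significant_pre_gate": n_sig_pre,
        "gated": len(gated),
        "significant_final": n_sig,
    }
    return PipelineResult(final, pool, summary, log)


def score_only(
    deg_a: DEGTable, deg_c: DEGTable, sig_threshold: float = 0.05
) -> pd.DataFrame:
    """Scores and quadrants without a permutation null; p-value, frequency
    and significance columns are empty."""
    records, _ = run_iit(deg_a, deg_c, sig_threshold)
    out = records.copy()
    for col in ("p_raw", "p_bonferroni"):
        out[col] = np.nan
    out["freq_count"] = np.nan
    out["freq_gated"] = ""
    out["significant"] = ""
    return out
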