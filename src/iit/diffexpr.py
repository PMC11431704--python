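"""Internal differential-expression engine.

A deliberately simple, fully specified stand-in for a negative-binomial DE
fit: library-size log-CPM normalization, a two-sample unequal-variance
(Welch) t test per gene, and Benjamini-Hochberg adjustment.  The original
disease-vs-healthy comparison may instead come from any external DE engine
via :func:`iit.dataio.read_deg_table`; the permutation null always uses this
engine so that a thousand refits stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import CountMatrix, DEGTable, SampleTable


@dataclass(frozen=True)
class DEConfig:
    """Settings for the internal DE engine.

    min_count
        A gene must reach this count in at least ``min_samples`` samples to
        survive the expression filter.
    min_samples
        Defaults (``None``) to the size of the smallest phenotype group used
        in the comparison at hand.
    prior_count
        Pseudo-count added before the log-CPM transform.
    variance_floor
        Lower bound for each group's variance in the Welch t statistic, so
        degenerate (zero-variance) groups cannot produce infinite t values.
    """

    min_count: int = 10
    min_samples: int | None = None
    prior_count: float = 0.5
    variance_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be non-negative")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be positive")
        if self.prior_count <= 0:
            raise ValueError("prior_count must be > 0")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")


def filter_low_expression(
    m: CountMatrix, cfg: DEConfig, smallest_group: int | None = None
) -> CountMatrix:
    """Keep genes with count >= min_count in >= min_samples samples.

    ``smallest_group`` supplies the default for ``cfg.min_samples`` when the
    config leaves it unset.
    """
    min_samples = cfg.min_samples if cfg.min_samples is not None else smallest_group
    if min_samples is None:
        raise ValueError(
            "min_samples unset and no smallest_group default provided"
        )
    keep = (m.counts >= cfg.min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    return m.subset_genes(keep)


def log_cpm(m: CountMatrix, prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a pseudo-count.

    entry = log2((count + prior) / (library_size + 2 * prior) * 1e6), where
    the library size is the per-sample column sum of the (filtered) matrix.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    lib = m.counts.sum(axis=0)
    if (lib == 0).any():
        j = int(np.argmax(lib == 0))
        raise ValueError(f"sample {m.sample_ids[j]!r} has zero library size")
    return np.log2(
        (m.counts + prior_count) / (lib + 2.0 * prior_count) * 1e6
    )


def welch_test(
    x: np.ndarray, y: np.ndarray, variance_floor: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t test of two sample blocks (genes x samples).

    Returns (mean(x) - mean(y), two-sided p).  Group variances are floored
    so all-equal groups give t = 0, p = 1 instead of 0/0.
    """
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    d = x.mean(axis=1) - y.mean(axis=1)
    v1 = np.maximum(x.var(axis=1, ddof=1), variance_floor)
    v2 = np.maximum(y.var(axis=1, ddof=1), variance_floor)
    se2 = v1 / n1 + v2 / n2
    t = d / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return d, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    m: CountMatrix,
    s: SampleTable,
    disease: str,
    cfg: DEConfig | None = None,
) -> DEGTable:
    """Disease-vs-healthy DE on an (already filtered) count matrix.

    Reports every gene in the matrix: log2fc is the difference of group mean
    log-CPMs, the p-value comes from a Welch t test on log-CPM, and fdr is
    the BH adjustment across all genes.
    """
    if disease not in ("cancer", "autoimmune"):
        raise ValueError("disease must be 'cancer' or 'autoimmune'")
    cfg = cfg or DEConfig()
    if tuple(s.sample_ids) != tuple(m.sample_ids):
        raise ValueError("metadata samples do not match count matrix samples")
    mask_d = s.mask(disease)
    mask_h = s.mask("healthy")
    if mask_d.sum() < 2 or mask_h.sum() < 2:
        raise ValueError(
            f"need >= 2 {disease} and >= 2 healthy samples "
            f"(got {int(mask_d.sum())} and {int(mask_h.sum())})"
        )
    lcpm = log_cpm(m, cfg.prior_count)
    return de_from_logcpm(lcpm, m.gene_ids, mask_d, mask_h, cfg, label=f"{disease}_vs_healthy")


def de_from_logcpm(
    lcpm: np.ndarray,
    gene_ids: tuple[str, ...],
    mask_disease: np.ndarray,
    mask_healthy: np.ndarray,
    cfg: DEConfig,
    label: str = "",
) -> DEGTable:
    """DE contrast on a precomputed log-CPM matrix (used by the permutation
    null, which recomputes two contrasts per replicate on fixed log-CPM)."""
    d, p = welch_test(
        lcpm[:, mask_disease], lcpm[:, mask_healthy], cfg.variance_floor
    )
    return DEGTable(tuple(gene_ids), d, p, bh_adjust(p), label)
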