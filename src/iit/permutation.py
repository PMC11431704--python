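"""Label-permutation null distribution, significance, and frequency gate.

Phenotype labels are randomly permuted over all samples jointly, both
disease-vs-healthy contrasts are refit with the internal engine, and the
immune-imbalance score is recomputed for the full gene universe.  Pooling
the permuted scores with the original scores, z-normalizing the pool, and
taking the upper-tail probability yields a per-gene p-value, corrected by
Bonferroni over the overlap pool.

The frequency gate targets batch noise: a gene whose permuted score clears
the (uncorrected) pooled significance cutoff in an unusually large number
of replicates is behaving like phenotype-independent noise and is removed
from the significant set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountMatrix, SampleTable
from .diffexpr import DEConfig, de_from_logcpm, log_cpm
from .scoring import score_weighted, weight_scores


@dataclass(frozen=True)
class NullDistribution:
    """Permuted scores for every (gene, replicate)."""

    n_perm: int
    gene_ids: tuple[str, ...]
    scores: np.ndarray  # shape (n_genes, n_perm), all >= 0
    seed: int

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.gene_ids), self.n_perm):
            raise ValueError(
                f"scores shape {scores.shape} != "
                f"({len(self.gene_ids)}, {self.n_perm})"
            )
        if (scores < 0).any():
            raise ValueError("permuted scores must be non-negative")

    @property
    def size(self) -> int:
        """Total permuted score count: genes x replicates."""
        return self.scores.size


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic child generator for one replicate, independent of how
    many replicates run or in what order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    )


def permute_labels(s: SampleTable, rng: np.random.Generator) -> SampleTable:
    """Uniform random permutation of the phenotype multiset over all samples
    jointly; sample and study identifiers stay put."""
    perm = rng.permutation(len(s))
    return s.with_phenotypes(tuple(s.phenotypes[i] for i in perm))


def build_null(
    m: CountMatrix,
    s: SampleTable,
    n_perm: int,
    seed: int,
    cfg: DEConfig | None = None,
) -> NullDistribution:
    """Permute labels, refit both contrasts, rescore; repeat ``n_perm`` times.

    ``m`` is the expression-filtered matrix; the scoring universe is all its
    genes (the internal engine reports every gene in both contrasts, so the
    shared set is the full universe).  log-CPM depends only on the counts and
    is computed once.
    """
    cfg = cfg or DEConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for ph in ("cancer", "autoimmune", "healthy"):
        if s.count(ph) < 2:
            raise ValueError(f"need >= 2 samples of phenotype {ph!r}")
    lcpm = log_cpm(m, cfg.prior_count)
    scores = np.empty((len(m.gene_ids), n_perm), dtype=float)
    for r in range(n_perm):
        try:
            rng = replicate_rng(seed, r)
            sp = permute_labels(s, rng)
            deg_a = de_from_logcpm(
                lcpm, m.gene_ids, sp.mask("autoimmune"), sp.mask("healthy"), cfg
            )
            deg_c = de_from_logcpm(
                lcpm, m.gene_ids, sp.mask("cancer"), sp.mask("healthy"), cfg
            )
            scores[:, r] = score_weighted(weight_scores(deg_a), weight_scores(deg_c))
        except Exception as exc:
            raise RuntimeError(f"permutation replicate {r} failed: {exc}") from exc
    return NullDistribution(n_perm, m.gene_ids, scores, seed)


def _pool(null: NullDistribution, original: np.ndarray | None) -> np.ndarray:
    parts = [null.scores.ravel()]
    if original is not None:
        parts.append(np.asarray(original, dtype=float))
    return np.concatenate(parts)


def pooled_pvalues(
    original: np.ndarray,
    null: NullDistribution,
    method: str = "normal",
) -> np.ndarray:
    """Upper-tail p-value of each original score against the pooled
    (null + original) score distribution.

    method="normal": z-score the pool (population sd) and take the standard
    normal upper tail of each original score's z — the literal procedure.
    method="empirical": p = (1 + #{pooled >= score}) / (1 + pool size), which
    makes no distributional assumption on the skewed score pool.
    """
    original = np.asarray(original, dtype=float)
    pool = _pool(null, original)
    if method == "normal":
        mu = pool.mean()
        sd = pool.std()
        if sd == 0:
            raise ValueError("pooled score distribution has zero sd")
        return stats.norm.sf((original - mu) / sd)
    if method == "empirical":
        srt = np.sort(pool)
        n_ge = len(srt) - np.searchsorted(srt, original, side="left")
        return (1.0 + n_ge) / (1.0 + len(srt))
    raise ValueError(f"unknown p-value method {method!r}")


def bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """min(p * m, 1) elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * m, 1.0)


def significance_cutoff(
    null: NullDistribution,
    original: np.ndarray | None = None,
    threshold: float = 0.05,
    method: str = "normal",
) -> float:
    """Score above which a pooled p-value falls below ``threshold``."""
    pool = _pool(null, original)
    if method == "normal":
        mu = pool.mean()
        sd = pool.std()
        if sd == 0:
            raise ValueError("pooled score distribution has zero sd")
        return float(mu + stats.norm.isf(threshold) * sd)
    if method == "empirical":
        srt = np.sort(pool)
        # smallest s with (1 + #{pool >= s}) / (1 + N) < threshold
        k = int(np.ceil(threshold * (1 + len(srt)) - 1))
        if k < 1:
            return float(srt[-1])
        return float(srt[len(srt) - k])
    raise ValueError(f"unknown p-value method {method!r}")


def frequency_counts(
    null: NullDistribution,
    original: np.ndarray | None = None,
    threshold: float = 0.05,
    method: str = "normal",
) -> np.ndarray:
    """Per gene: in how many replicates its permuted score is significant
    under the uncorrected pooled rule (pooled p < threshold)."""
    cut = significance_cutoff(null, original, threshold, method)
    return (null.scores > cut).sum(axis=1)


def frequency_gate(
    gene_ids: tuple[str, ...], counts: np.ndarray, alpha: float = 0.05
) -> tuple[set[str], np.ndarray]:
    """Gate genes whose frequency count is an upper-tail outlier.

    Counts are z-normalized (population sd); a gene is gated when the
    standard-normal upper-tail probability of its z falls below ``alpha``.
    Constant counts gate nothing.  Returns (gated gene set, per-gene p).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(gene_ids),):
        raise ValueError("counts must align with gene_ids")
    sd = counts.std()
    if sd == 0:
        return set(), np.ones_like(counts)
    p = stats.norm.sf((counts - counts.mean()) / sd)
    gated = {g for g, pv in zip(gene_ids, p) if pv < alpha}
    return gated, p


def finalize_significance(
    records: pd.DataFrame,
    overlap_pool: set[str],
    p_raw: np.ndarray,
    freq_count: np.ndarray,
    freq_p: np.ndarray,
    gated: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-gene significance table.

    Bonferroni m is the overlap-pool size (significance is only asserted
    within the pool); a gene is significant iff it is in the pool, its
    corrected p is below ``alpha``, and it is not frequency-gated.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    if len(p_raw) != len(records):
        raise ValueError("p_raw must align with records")
    m = max(len(overlap_pool), 1)
    p_bonf = bonferroni(p_raw, m)
    genes = records["gene_id"].to_numpy()
    in_pool = np.array([g in overlap_pool for g in genes])
    is_gated = np.array([g in gated for g in genes])
    out = records.copy()
    out["p_raw"] = p_raw
    out["p_bonferroni"] = p_bonf
    out["freq_count"] = np.asarray(freq_count, dtype=int)
    out["freq_p"] = np.asarray(freq_p, dtype=float)
    out["freq_gated"] = is_gated
    out["significant"] = in_pool & (p_bonf < alpha) & ~is_gated
    return out
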