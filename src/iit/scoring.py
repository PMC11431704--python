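"""The immune-imbalance score.

For each gene shared by an autoimmune-vs-healthy and a cancer-vs-healthy
differential-expression table:

1. weight:       w = log2FC * (-log10 FDR)
2. z-normalize each comparison's weights across all shared genes
3. magnitude:    abs = sqrt(z^2) = |z|
4. intermediate: abs_a + abs_c
5. ratio:        min(abs_a/abs_c, abs_c/abs_a)  (0 if either magnitude is 0)
6. score:        intermediate * ratio

The ratio weighting favors genes dysregulated to a *similar* degree in the
two diseases: for fixed abs_a = a the score is maximized (value 2a) when
abs_c = a, and the score never exceeds 2 * min(abs_a, abs_c).

Quadrants classify the raw fold-change signs: I = up in both (C+A+),
II = up in cancer only (C+A-), III = down in both (C-A-), IV = up in
autoimmune only (C-A+).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import DEGTable

QUADRANTS = ("I", "II", "III", "IV")

#: Absolute lower bound when flooring FDR values of exactly zero.
FDR_ABS_FLOOR = 1e-300


def floor_fdr(fdr: np.ndarray) -> np.ndarray:
    """Replace FDR values of exactly 0 (numerical underflow) by half the
    smallest nonzero FDR in the same table, bounded below by 1e-300.

    Keeps -log10(FDR) finite while preserving the significance ordering.
    """
    fdr = np.asarray(fdr, dtype=float)
    out = fdr.copy()
    zero = fdr == 0.0
    if zero.any():
        nonzero = fdr[~zero]
        repl = nonzero.min() / 2.0 if nonzero.size else FDR_ABS_FLOOR
        out[zero] = max(repl, FDR_ABS_FLOOR)
    return out


def weight_scores(t: DEGTable) -> np.ndarray:
    """FDR-weighted fold changes: w = log2FC * (-log10 FDR), aligned with
    ``t.gene_ids``.  The sign of w equals the sign of log2FC; FDR = 1 gives
    w = 0 regardless of fold change."""
    return t.log2fc * (-np.log10(floor_fdr(t.fdr)))


def znormalize(v: np.ndarray) -> np.ndarray:
    """(v - mean) / sd with population sd (divisor n)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to z-normalize")
    sd = v.std()  # population sd
    if sd == 0:
        raise ValueError("cannot z-normalize a constant vector")
    return (v - v.mean()) / sd


def iit_score(
    z_a: np.ndarray | float, z_c: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Score from the two z-normalized weighted values.

    Returns (abs_a, abs_c, intermediate, ratio, score); accepts scalars or
    aligned arrays.  If either magnitude is 0 the ratio (and hence the
    score) is 0 by convention: a gene not dysregulated in one disease shows
    no shared imbalance.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    # sqrt(z^2) evaluated as |z|: identical mathematically, but immune to
    # underflow of the intermediate square
    abs_a = np.abs(z_a)
    abs_c = np.abs(z_c)
    intermediate = abs_a + abs_c
    both = (abs_a > 0) & (abs_c > 0)
    # the larger quotient may overflow to inf; min() discards it
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(
            both,
            np.minimum(
                np.divide(abs_a, abs_c, out=np.zeros_like(abs_a), where=abs_c > 0),
                np.divide(abs_c, abs_a, out=np.zeros_like(abs_c), where=abs_a > 0),
            ),
            0.0,
        )
    score = intermediate * ratio
    return abs_a, abs_c, intermediate, ratio, score


def assign_quadrant(
    log2fc_a: np.ndarray | float, log2fc_c: np.ndarray | float
) -> np.ndarray:
    """Quadrant from the (cancer, autoimmune) fold-change signs; any exact
    zero yields "none"."""
    a = np.atleast_1d(np.asarray(log2fc_a, dtype=float))
    c = np.atleast_1d(np.asarray(log2fc_c, dtype=float))
    out = np.full(a.shape, "none", dtype=object)
    out[(c > 0) & (a > 0)] = "I"
    out[(c > 0) & (a < 0)] = "II"
    out[(c < 0) & (a < 0)] = "III"
    out[(c < 0) & (a > 0)] = "IV"
    return out


def score_weighted(w_a: np.ndarray, w_c: np.ndarray) -> np.ndarray:
    """z-normalize two aligned weight vectors and return the final scores.

    Convenience path used per permutation replicate."""
    z_a = znormalize(w_a)
    z_c = znormalize(w_c)
    return iit_score(z_a, z_c)[4]


def run_iit(
    deg_a: DEGTable, deg_c: DEGTable, sig_threshold: float = 0.05
) -> tuple[pd.DataFrame, set[str]]:
    """Score every gene shared by the two DEG tables.

    Weighting and z-normalization run over the *full* shared-gene set; the
    overlap pool (genes with FDR < ``sig_threshold`` in BOTH comparisons) is
    where significance is later asserted.  Returns the per-gene record table
    (in ``deg_a``'s gene order restricted to shared genes) and the overlap
    pool as a set.
    """
    shared = [g for g in deg_a.gene_ids if g in set(deg_c.gene_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 genes shared between the two DEG tables, got {len(shared)}"
        )
    a = deg_a.subset(shared)
    c = deg_c.subset(shared)
    w_a = weight_scores(a)
    w_c = weight_scores(c)
    z_a = znormalize(w_a)
    z_c = znormalize(w_c)
    abs_a, abs_c, intermediate, ratio, score = iit_score(z_a, z_c)
    records = pd.DataFrame(
        {
            "gene_id": shared,
            "log2fc_autoimmune": a.log2fc,
            "fdr_autoimmune": a.fdr,
            "log2fc_cancer": c.log2fc,
            "fdr_cancer": c.fdr,
            "w_autoimmune": w_a,
            "w_cancer": w_c,
            "z_autoimmune": z_a,
            "z_cancer": z_c,
            "abs_autoimmune": abs_a,
            "abs_cancer": abs_c,
            "intermediate": intermediate,
            "ratio": ratio,
            "iit_score": score,
            "quadrant": assign_quadrant(a.log2fc, c.log2fc),
        }
    )
    pool = {
        g
        for g, fa, fc in zip(shared, a.fdr, c.fdr)
        if fa < sig_threshold and fc < sig_threshold
    }
    return records, pool
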