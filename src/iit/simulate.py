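"""Synthetic three-phenotype count data with known ground truth.

Counts follow a negative binomial with a shared dispersion; planted genes
receive signed log2 mean shifts per disease according to their quadrant
profile (I: up in both; II: up in cancer, down in autoimmune; III: down in
both; IV: down in cancer, up in autoimmune).  Healthy samples never carry a
disease effect.  Optional study-level batch effects add a per-(gene, study)
log2 shift, uncorrelated with phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CountMatrix, SampleTable
from .scoring import QUADRANTS

#: Sign of (cancer effect, autoimmune effect) per quadrant profile.
QUADRANT_SIGNS = {
    "I": (1.0, 1.0),
    "II": (1.0, -1.0),
    "III": (-1.0, -1.0),
    "IV": (-1.0, 1.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    n_per_group is (cancer, autoimmune, healthy).  ``planted`` maps each
    quadrant to (gene count, (lo, hi) range of |log2 effect|).  The
    defaults produce 1000 genes with 25 planted per quadrant at |log2FC|
    1.5-2.5 and 20 samples per group — a moderately powered bulk RNA-seq
    three-group design.  nb_dispersion 0.1 corresponds to a biological
    coefficient of variation of ~0.32, typical for heterogeneous human
    cohorts; baseline means are uniform over 10-1000 counts.
    """

    n_genes: int = 1000
    n_per_group: tuple[int, int, int] = (20, 20, 20)
    planted: dict[str, tuple[int, tuple[float, float]]] = field(
        default_factory=lambda: {q: (25, (1.5, 2.5)) for q in QUADRANTS}
    )
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (10.0, 1000.0)
    batch: tuple[int, float] | None = None  # (n_studies, log2 shift sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each phenotype group needs >= 2 samples")
        total_planted = sum(n for n, _ in self.planted.values())
        if total_planted > self.n_genes:
            raise ValueError(
                f"planted gene count {total_planted} exceeds n_genes {self.n_genes}"
            )
        for q in self.planted:
            if q not in QUADRANT_SIGNS:
                raise ValueError(f"unknown quadrant {q!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_mean_range must be a positive interval")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + disp*mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """Generate (counts, metadata, truth table) from the config.

    The truth table has one row per gene: planted_quadrant in
    {I, II, III, IV, null} and the signed log2 effects (effect_a, effect_c)
    actually applied; null genes carry zero effects.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = tuple(f"G{i:05d}" for i in range(cfg.n_genes))
    n_c, n_a, n_h = cfg.n_per_group
    sample_ids = tuple(
        [f"C{i:03d}" for i in range(n_c)]
        + [f"A{i:03d}" for i in range(n_a)]
        + [f"H{i:03d}" for i in range(n_h)]
    )
    phenotypes = tuple(
        ["cancer"] * n_c + ["autoimmune"] * n_a + ["healthy"] * n_h
    )

    mu = rng.uniform(*cfg.baseline_mean_range, size=cfg.n_genes)

    effect_c = np.zeros(cfg.n_genes)
    effect_a = np.zeros(cfg.n_genes)
    truth_quadrant = np.array(["null"] * cfg.n_genes, dtype=object)
    pos = 0
    for q in QUADRANTS:
        if q not in cfg.planted:
            continue
        n_q, (lo, hi) = cfg.planted[q]
        sign_c, sign_a = QUADRANT_SIGNS[q]
        idx = slice(pos, pos + n_q)
        effect_c[idx] = sign_c * rng.uniform(lo, hi, size=n_q)
        effect_a[idx] = sign_a * rng.uniform(lo, hi, size=n_q)
        truth_quadrant[idx] = q
        pos += n_q

    # per-sample log2 shift: disease effect by phenotype, zero for healthy
    shift = np.zeros((cfg.n_genes, len(sample_ids)))
    pheno_arr = np.array(phenotypes)
    shift[:, pheno_arr == "cancer"] = effect_c[:, None]
    shift[:, pheno_arr == "autoimmune"] = effect_a[:, None]

    study_ids = None
    if cfg.batch is not None:
        n_studies, sd = cfg.batch
        assignment = np.arange(len(sample_ids)) % n_studies
        study_ids = tuple(f"S{k:02d}" for k in assignment)
        study_shift = rng.normal(0.0, sd, size=(cfg.n_genes, n_studies))
        shift = shift + study_shift[:, assignment]

    mean = mu[:, None] * np.exp2(shift)
    counts = _nb_draw(rng, mean, cfg.nb_dispersion).astype(np.int64)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_quadrant": truth_quadrant,
            "effect_a": effect_a,
            "effect_c": effect_c,
        }
    )
    return (
        CountMatrix(gene_ids, sample_ids, counts),
        SampleTable(sample_ids, phenotypes, study_ids),
        truth,
    )


def inject_frequency_noise(
    m: CountMatrix,
    gene_ids: set[str] | frozenset[str],
    inflation: float,
    rng: np.random.Generator,
) -> CountMatrix:
    """Multiply selected genes' counts by phenotype-independent log-normal
    noise (2^N(0, inflation) per cell), emulating batch-effect noise that the
    frequency gate is designed to catch.  inflation = 0 returns the counts
    unchanged."""
    unknown = set(gene_ids) - set(m.gene_ids)
    if unknown:
        raise ValueError(f"unknown gene ids: {sorted(unknown)[:5]}")
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    counts = m.counts.copy()
    if inflation > 0:
        rows = [i for i, g in enumerate(m.gene_ids) if g in gene_ids]
        noise = np.exp2(
            rng.normal(0.0, inflation, size=(len(rows), len(m.sample_ids)))
        )
        counts[rows] = np.rint(counts[rows] * noise).astype(np.int64)
    return CountMatrix(m.gene_ids, m.sample_ids, counts)
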