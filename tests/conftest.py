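import numpy as np
import pandas as pd
import pytest

from iit.dataio import CountMatrix, DEGTable, SampleTable

# Published top-four genes per quadrant from the lupus/lymphoma B-cell
# comparison: (gene, lupus log2FC, lupus FDR, lymphoma log2FC, lymphoma FDR,
# quadrant).  Used as a worked input set throughout the tests.
TOP_GENES = [
    ("TPM2", 1.85, 3.25e-8, 3.88, 1.65e-25, "I"),
    ("PTMS", 2.03, 2.05e-10, 3.72, 8.08e-27, "I"),
    ("PLXNA1", 1.11, 3.14e-12, 2.75, 1.04e-34, "I"),
    ("SIX5", 1.72, 5.53e-12, 2.79, 7.36e-34, "I"),
    ("LGALS3BP", -1.57, 3.57e-10, 3.55, 3.62e-36, "II"),
    ("VSIG4", -1.65, 5.81e-8, 6.13, 4.83e-29, "II"),
    ("FKBP5", -1.33, 1.77e-9, 2.25, 8.87e-36, "II"),
    ("ARMCX1", -1.19, 8.57e-7, 2.87, 3.10e-22, "II"),
    ("MED30", -0.895, 1.54e-12, -1.46, 5.07e-41, "III"),
    ("ING3", -0.983, 1.58e-17, -1.63, 3.96e-40, "III"),
    ("OSER1", -0.752, 6.09e-14, -1.6, 8.45e-50, "III"),
    ("PLD4", -1.05, 2.23e-10, -3.5, 6.43e-26, "III"),
    ("PNRC1", 1.21, 5.07e-16, -2.11, 1.16e-43, "IV"),
    ("SLC12A6", 1.04, 6.91e-15, -2.46, 3.48e-37, "IV"),
    ("OTUD1", 1.47, 7.92e-18, -2.24, 5.46e-37, "IV"),
    ("MARCH8", 0.932, 6.91e-15, -1.86, 5.35e-40, "IV"),
]


@pytest.fixture(scope="session")
def top_gene_tables() -> tuple[DEGTable, DEGTable]:
    """(autoimmune, cancer) DEG tables built from the published top genes."""
    genes = tuple(r[0] for r in TOP_GENES)
    a = DEGTable(
        genes,
        np.array([r[1] for r in TOP_GENES]),
        np.array([r[2] for r in TOP_GENES]),
        np.array([r[2] for r in TOP_GENES]),
        "autoimmune_vs_healthy",
    )
    c = DEGTable(
        genes,
        np.array([r[3] for r in TOP_GENES]),
        np.array([r[4] for r in TOP_GENES]),
        np.array([r[4] for r in TOP_GENES]),
        "cancer_vs_healthy",
    )
    return a, c


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(99)
    counts = rng.integers(0, 500, size=(12, 8))
    return CountMatrix(
        tuple(f"g{i}" for i in range(12)),
        tuple(f"s{j}" for j in range(8)),
        counts,
    )


@pytest.fixture
def small_samples() -> SampleTable:
    return SampleTable(
        tuple(f"s{j}" for j in range(8)),
        ("cancer", "cancer", "cancer", "autoimmune", "autoimmune", "healthy",
         "healthy", "healthy"),
    )


@pytest.fixture
def deg_pair() -> tuple[DEGTable, DEGTable]:
    """10-gene hand-set DEG tables used for end-to-end score checks."""
    genes = tuple(f"g{i}" for i in range(10))
    rng = np.random.default_rng(7)
    log2fc_a = np.array([2.0, -1.5, 0.8, -0.3, 1.2, 3.1, -2.2, 0.05, -0.9, 1.7])
    log2fc_c = np.array([1.8, 1.1, -0.7, -0.4, 1.3, -2.9, -2.0, 2.5, 0.1, 1.6])
    fdr_a = np.array([1e-10, 1e-4, 0.2, 0.9, 1e-6, 1e-20, 1e-8, 0.99, 0.04, 1e-3])
    fdr_c = np.array([1e-12, 0.03, 0.5, 0.8, 1e-7, 1e-15, 1e-9, 1e-5, 0.95, 1e-2])
    p_a = fdr_a / 2
    p_c = fdr_c / 2
    a = DEGTable(genes, log2fc_a, p_a, fdr_a, "autoimmune_vs_healthy")
    c = DEGTable(genes, log2fc_c, p_c, fdr_c, "cancer_vs_healthy")
    return a, c
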