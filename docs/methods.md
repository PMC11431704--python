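# Methods

## The model

`iit` treats a gene's cross-disease behavior as a two-dimensional quantity:
its differential expression in an autoimmune-vs-healthy contrast and in a
cancer-vs-healthy contrast from the same tissue. The score collapses this
to one number that rewards *balanced* dysregulation. Writing
`w = log2FC × (−log10 FDR)` for each contrast and `z_A`, `z_C` for the
per-contrast standardized weights,

    score = (|z_A| + |z_C|) × min(|z_A|/|z_C|, |z_C|/|z_A|).

Useful identities: the score equals `2·min(|z_A|, |z_C|)` exactly when
`|z_A| = |z_C|`, never exceeds that bound, is symmetric in the two
contrasts, and scales linearly if both z-vectors are scaled together. For
fixed `|z_A| = a`, the score is strictly increasing in `|z_C|` on `(0, a]`
and strictly decreasing beyond — the formal statement of the
similar-intensity preference. If either magnitude is exactly 0 the ratio
(and the score) is defined as 0: a gene dysregulated in only one disease
carries no shared-imbalance evidence.

Assumptions worth keeping in mind: the two DEG tables must come from the
same gene universe and tissue; z-normalization makes scores *relative*
quantities, comparable within one analysis but not across datasets; and
the FDR weighting presumes the upstream DE engine produced calibrated
FDR values.

## Differential expression engine

The original comparisons may be ingested from any external DE tool as TSV
tables. The built-in engine — used for the original contrasts when no
tables are supplied, and always inside the permutation null, where
thousands of refits must be cheap — is deliberately simple and fully
specified:

- log2 CPM with a pseudo-count:
  `log2((count + c0) / (library + 2·c0) × 1e6)`, `c0 = 0.5` by default.
  No TMM or median-of-ratios size factors; the library size is the column
  sum of the filtered matrix.
- per-gene Welch (unequal-variance) t test on log-CPM, with each group
  variance floored at `1e-8` so degenerate zero-variance groups give
  t = 0, p = 1 rather than 0/0.
- Benjamini–Hochberg adjustment across all reported genes.

An expression filter (count ≥ `min_count` in ≥ `min_samples` samples;
defaults 10 and the smallest phenotype-group size) runs once per dataset,
before any contrast. This engine is not a negative-binomial fit; its role
is to rank and weight genes consistently between the original analysis and
the permutation null, which is what the downstream score consumes.

## Permutation null and significance

Phenotype labels are permuted uniformly over all samples jointly
(`n_perm` replicates; replicate `r` draws from a child generator spawned
as `SeedSequence(seed, spawn_key=(r,))`, so results are independent of
replicate order and count). Both contrasts are refit per replicate on the
precomputed log-CPM matrix and the full gene universe is rescored, giving
`G × n_perm` permuted scores.

Permuted and original scores are pooled; each original score receives an
upper-tail p-value against the pool. Two methods are provided:

- `normal` — z-score the pool (population sd) and take the standard-normal
  upper tail. This is the literal published procedure, but on null-heavy
  data the score pool is strongly right-skewed with a point mass near
  zero, and the normal tail is then *conservative* (we measure a mean
  fraction of ~0.03 of null genes at p < 0.05 instead of 0.05).
- `empirical` — `p = (1 + #{pooled ≥ s}) / (1 + pool size)`. Calibrated by
  construction up to discreteness; preferred when the null matters.

The default remains `normal` for fidelity; calibration-sensitive analyses
should pass `--p-method empirical`.

A caution for interpretation: the per-dataset *fraction* of genes below
any p threshold is far more variable than a binomial count, because every
gene's p-value shares the single original scoring replicate, and that
replicate's score-distribution shape (spiky when BH leaves most FDRs at 1,
diffuse otherwise) fluctuates as a unit. Calibration statements in the
test suite therefore average over independent datasets.

Bonferroni correction uses `m = |overlap pool|` — the genes with
FDR < `sig_threshold` (default 0.05) in both original comparisons — since
significance is only ever asserted within that pool.

## Frequency gate

For each gene we count the replicates in which its permuted score clears
the *uncorrected* pooled p < 0.05 cutoff. A gene whose count is an
upper-tail outlier is behaving like phenotype-independent noise — its
score rises regardless of how labels are assigned — and is removed from
the significant set.

The z-normalization population for the gate is the pre-gate significant
set (genes in the overlap pool with Bonferroni p < alpha), matching the
published narrative in which counts are examined for the significant
genes and a small fraction of them is removed. Normalizing over the whole
universe instead would make every strongly disease-associated gene an
outlier: truly planted genes retain diluted signal under label
permutation (a permuted "cancer" group still contains a random share of
true cancer samples), so their counts sit well above pure-null genes'
even without any batch noise. On clean synthetic data that choice gates
~90 % of true positives; within the significant set it removes only the
count outliers. `frequency_gate` itself is population-agnostic (counts in,
gated set out), so either convention can be composed from the primitives.
Constant counts gate nothing by convention.

## Synthetic data generator

`simulate_dataset` emulates the three-phenotype bulk RNA-seq design:
counts are negative binomial with a single shared dispersion
(default 0.1, a biological CV of ~0.32 — typical for heterogeneous human
cohorts), baseline means uniform on 10–1000, and planted genes receive
signed log2 mean shifts per quadrant profile (I: +C +A, II: +C −A,
III: −C −A, IV: −C +A) with magnitudes drawn from a stated range. Healthy
samples never carry disease effects. Defaults — 1000 genes, 25 planted
per quadrant at |log2FC| ∈ [1.5, 2.5], 20 samples per group — define the
study conditions used by the recovery analyses. Optional study-level
batch effects add per-(gene, study) log2 shifts with samples assigned to
studies round-robin.

`inject_frequency_noise` multiplies selected genes' counts by
`2^N(0, sd)` per cell — phenotype-independent multiplicative noise. Note
that such iid noise is *pivotal* for the Welch t statistic: it inflates
fold-change magnitudes but not t, so it raises the FDR-weighted products
of null genes (whose permuted weights then reach the pooled tail more
often — the regime the gate detects) while for planted genes it largely
cancels against the suppressed dilution signal. The gate experiments use
noise sd 0.5 in log2, comparable to the biological variation implied by
the default dispersion. What the generator does *not* model: per-gene
dispersion trends, library-size imbalance, correlated gene modules, or
study-level confounding between batch and phenotype — so passing recovery
tests demonstrate correctness of the machinery under the stated model,
not performance on arbitrary real compendia.

## Numerical choices

- FDR values of exactly 0 (printed underflow) are replaced by half the
  smallest nonzero FDR in the same table, floored at 1e-300, keeping
  −log10 finite and order-preserving.
- z-normalization uses the population sd (divisor n) throughout — for the
  weighted products, the pooled null, and the frequency counts — and
  raises on constant input (except the gate, which returns an empty set).
- `|z|` is computed as `abs(z)` rather than `sqrt(z**2)` to avoid
  underflow of the intermediate square; the quantities are identical.
- Quadrants require strictly nonzero fold changes; any exact zero maps to
  "none" (kept in scoring, excluded from quadrant counts).
- PCA QC z-normalizes counts per gene, drops constant genes, and fixes
  component signs by making each component's largest-magnitude gene
  loading positive, so coordinates are bit-reproducible.
- All randomness flows from explicit seeds; identical inputs and seeds
  give byte-identical result files.

## Problem sizes in the checks

The acceptance analyses run at: 50 genes × 10 permutations for the
bookkeeping identities; the generator defaults (1000 genes, 100 planted,
20/20/20 samples) with 100 permutations for recovery; 100 independent
2000-gene null datasets at 100 permutations for calibration; and 1000
genes (100 noise-injected) at 100 permutations for the gate experiment.
These sizes were chosen to estimate each quantity stably while keeping a
full run in the minutes range on one CPU.

## Known limitations

- The internal DE engine is a log-CPM t-test stand-in, not a
  count-model fit; absolute FDR values differ from negative-binomial
  engines, though the downstream score only needs consistent weighting.
- The normal-tail p-value method is conservative on skewed null pools
  (see above).
- The frequency gate assumes batch noise is phenotype-independent; batch
  structure confounded with phenotype is not corrected (by design — the
  published workflow deliberately avoids study-level batch correction).
- Known-drug-target annotation consumes local TSV exports only; no
  network access, and database versioning is the caller's concern.
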