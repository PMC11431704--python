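"""Permutation null, pooled p-values, Bonferroni, frequency gate."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from iit.dataio import SampleTable
from iit.diffexpr import DEConfig
from iit.permutation import (
    NullDistribution,
    bonferroni,
    build_null,
    finalize_significance,
    frequency_counts,
    frequency_gate,
    permute_labels,
    pooled_pvalues,
    replicate_rng,
    significance_cutoff,
)
from iit.scoring import run_iit
from iit.diffexpr import differential_expression, filter_low_expression
from iit.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="module")
def tiny_null():
    """Small filtered dataset plus its null distribution."""
    m, s, _ = simulate_dataset(
        SimConfig(
            n_genes=60,
            n_per_group=(5, 5, 5),
            planted={},
            baseline_mean_range=(100.0, 1000.0),
            seed=2,
        )
    )
    cfg = DEConfig()
    mf = filter_low_expression(m, cfg, smallest_group=5)
    null = build_null(mf, s, n_perm=10, seed=21, cfg=cfg)
    deg_a = differential_expression(mf, s, "autoimmune", cfg)
    deg_c = differential_expression(mf, s, "cancer", cfg)
    rec, pool = run_iit(deg_a, deg_c)
    return mf, s, null, rec, pool


class TestPermuteLabels:
    def test_multiset_conserved(self):
        s = SampleTable(
            tuple(f"s{i}" for i in range(9)),
            ("cancer",) * 3 + ("autoimmune",) * 3 + ("healthy",) * 3,
        )
        out = permute_labels(s, np.random.default_rng(4))
        assert Counter(out.phenotypes) == Counter(s.phenotypes)
        assert out.sample_ids == s.sample_ids

    def test_deterministic_under_same_state(self):
        s = SampleTable(
            tuple(f"s{i}" for i in range(6)),
            ("cancer", "cancer", "autoimmune", "autoimmune", "healthy", "healthy"),
        )
        a = permute_labels(s, np.random.default_rng(11))
        b = permute_labels(s, np.random.default_rng(11))
        assert a.phenotypes == b.phenotypes

    def test_uniform_over_label_arrangements(self):
        """6 samples, 3 labels x 2: all 6!/(2!2!2!) = 90 arrangements equally
        likely (chi-square goodness of fit at alpha = 0.01)."""
        s = SampleTable(
            tuple(f"s{i}" for i in range(6)),
            ("cancer", "cancer", "autoimmune", "autoimmune", "healthy", "healthy"),
        )
        arrangements = sorted(set(itertools.permutations(s.phenotypes)))
        assert len(arrangements) == 90
        rng = np.random.default_rng(8)
        draws = Counter(permute_labels(s, rng).phenotypes for _ in range(9000))
        observed = np.array([draws.get(a, 0) for a in arrangements])
        chi2 = ((observed - 100) ** 2 / 100).sum()
        assert chi2 < stats.chi2.isf(0.01, df=89)


class TestBuildNull:
    def test_score_count_is_genes_times_replicates(self, tiny_null):
        _, _, null, _, _ = tiny_null
        assert null.size == len(null.gene_ids) * null.n_perm

    def test_bit_identical_for_same_seed(self, tiny_null):
        mf, s, null, _, _ = tiny_null
        again = build_null(mf, s, n_perm=10, seed=21, cfg=DEConfig())
        np.testing.assert_array_equal(null.scores, again.scores)

    def test_scores_non_negative(self, tiny_null):
        assert (tiny_null[2].scores >= 0).all()

    def test_replicates_independent_of_total(self, tiny_null):
        """Replicate r's scores do not change when n_perm grows."""
        mf, s, null, _, _ = tiny_null
        longer = build_null(mf, s, n_perm=12, seed=21, cfg=DEConfig())
        np.testing.assert_array_equal(null.scores, longer.scores[:, :10])

    def test_child_seeds_distinct(self):
        a = replicate_rng(5, 0).integers(0, 2**31, 4)
        b = replicate_rng(5, 1).integers(0, 2**31, 4)
        assert not np.array_equal(a, b)


class TestPooledPvalues:
    @staticmethod
    def _null_from(scores):
        scores = np.asarray(scores, float)
        return NullDistribution(
            scores.shape[1],
            tuple(f"g{i}" for i in range(scores.shape[0])),
            scores,
            seed=0,
        )

    def test_pool_mean_maps_to_half(self):
        rng = np.random.default_rng(0)
        null = self._null_from(np.abs(rng.normal(size=(50, 40))))
        pool = np.concatenate([null.scores.ravel(), [0.0]])
        # one original score placed exactly at the pooled mean
        target = pool.mean()
        # iterate once: mean of pool including the original shifts slightly
        for _ in range(50):
            target = np.concatenate([null.scores.ravel(), [target]]).mean()
        p = pooled_pvalues(np.array([target]), null, method="normal")
        assert p[0] == pytest.approx(0.5, abs=1e-9)

    def test_score_at_1645_sd_maps_to_005(self):
        rng = np.random.default_rng(1)
        null = self._null_from(np.abs(rng.normal(size=(200, 100))))
        probe = np.array([0.0])
        for _ in range(80):  # fixed point of pool including the probe
            pool = np.concatenate([null.scores.ravel(), probe])
            probe = np.array([pool.mean() + 1.6448536269514722 * pool.std()])
        p = pooled_pvalues(probe, null, method="normal")
        assert p[0] == pytest.approx(0.05, abs=1e-4)

    def test_strictly_decreasing_in_score(self):
        rng = np.random.default_rng(2)
        null = self._null_from(np.abs(rng.normal(size=(30, 30))))
        orig = np.array([0.1, 0.5, 1.0, 2.0, 4.0])
        for method in ("normal", "empirical"):
            p = pooled_pvalues(orig, null, method=method)
            assert (np.diff(p) < 0).all() or (
                method == "empirical" and (np.diff(p) <= 0).all()
            )

    def test_empirical_matches_brute_force_count(self):
        rng = np.random.default_rng(3)
        null = self._null_from(np.abs(rng.normal(size=(20, 10))))
        orig = np.abs(rng.normal(size=20))
        p = pooled_pvalues(orig, null, method="empirical")
        pool = np.concatenate([null.scores.ravel(), orig])
        expected = np.array(
            [(1 + (pool >= s).sum()) / (1 + len(pool)) for s in orig]
        )
        np.testing.assert_allclose(p, expected)

    def test_zero_sd_pool_rejected(self):
        null = self._null_from(np.ones((5, 5)))
        with pytest.raises(ValueError, match="zero sd"):
            pooled_pvalues(np.ones(5), null, method="normal")


class TestBonferroni:
    def test_scales_and_caps(self):
        np.testing.assert_allclose(bonferroni(np.array([0.01]), 10), [0.1])
        np.testing.assert_allclose(bonferroni(np.array([0.2]), 10), [1.0])

    def test_overlap_pool_sized_correction(self):
        # m matching the reported joint-significant pool of 7143 genes
        assert bonferroni(np.array([1e-6]), 7143)[0] == pytest.approx(7.143e-3)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError, match="m"):
            bonferroni(np.array([0.5]), 0)


class TestFrequencyCounts:
    def test_near_equal_scores_yield_zero_counts(self):
        # all scores equal except a handful slightly lower: the cutoff
        # (pool mean + 1.645 sd) lands above the maximum, so nothing counts
        scores = np.full((10, 20), 1.0)
        scores[0, :3] = 1.0 - 1e-6
        null = NullDistribution(20, tuple(f"g{i}" for i in range(10)), scores, 0)
        counts = frequency_counts(null, threshold=0.05)
        assert (counts == 0).all()

    def test_inflated_gene_counted_at_inflation_rate(self):
        """A gene whose permuted score is pushed into the extreme tail in 40%
        of replicates gets a count near 0.4 * n_perm."""
        rng = np.random.default_rng(5)
        n_perm = 400
        scores = np.abs(rng.normal(size=(200, n_perm)))
        hot = rng.random(n_perm) < 0.4
        scores[0, hot] = 30.0
        null = NullDistribution(n_perm, tuple(f"g{i}" for i in range(200)), scores, 0)
        counts = frequency_counts(null, threshold=0.05)
        assert counts[0] == hot.sum()
        lo, hi = stats.binom.interval(0.99, n_perm, 0.4)
        assert lo <= counts[0] <= hi

    def test_counts_invariant_to_gene_order(self):
        rng = np.random.default_rng(6)
        scores = np.abs(rng.normal(size=(15, 30)))
        genes = tuple(f"g{i}" for i in range(15))
        null = NullDistribution(30, genes, scores, 0)
        perm = rng.permutation(15)
        null_p = NullDistribution(30, tuple(genes[i] for i in perm), scores[perm], 0)
        c1 = frequency_counts(null)
        c2 = frequency_counts(null_p)
        np.testing.assert_array_equal(c1[perm], c2)


class TestFrequencyGate:
    def test_hand_computed_outlier(self):
        # counts [10,10,10,10,90]: mean 26, population sd 32, z(90) = 2.0,
        # upper-tail p ~ 0.0228 < 0.05 -> gated; others z = -0.5 -> kept
        genes = ("a", "b", "c", "d", "e")
        gated, p = frequency_gate(genes, np.array([10, 10, 10, 10, 90]), 0.05)
        assert gated == {"e"}
        assert p[4] == pytest.approx(stats.norm.sf(2.0), abs=1e-9)
        assert p[0] == pytest.approx(stats.norm.sf(-0.5), abs=1e-9)

    def test_constant_counts_gate_nothing(self):
        gated, p = frequency_gate(("a", "b", "c"), np.array([7, 7, 7]), 0.05)
        assert gated == set()
        assert (p == 1.0).all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 50, size=30)
        genes = tuple(f"g{i}" for i in range(30))
        g1, _ = frequency_gate(genes, counts, 0.05)
        g2, _ = frequency_gate(genes, counts + 17, 0.05)
        assert g1 == g2


class TestFinalizeSignificance:
    def test_pool_membership_and_gate_are_required(self, tiny_null):
        _, _, null, rec, pool = tiny_null
        p_raw = np.full(len(rec), 1e-9)  # tiny for everyone
        counts = np.zeros(len(rec))
        gated = {rec["gene_id"].iloc[0]}
        out = finalize_significance(
            rec, pool, p_raw, counts, np.ones(len(rec)), gated, alpha=0.05
        )
        outside = ~out["gene_id"].isin(pool)
        assert not out.loc[outside, "significant"].any()
        assert not out.loc[out["gene_id"].isin(gated), "significant"].any()
        in_pool_ungated = out["gene_id"].isin(pool) & ~out["gene_id"].isin(gated)
        assert out.loc[in_pool_ungated, "significant"].all()

    def test_bonferroni_uses_pool_size(self, tiny_null):
        _, _, _, rec, pool = tiny_null
        p_raw = np.linspace(0.001, 0.9, len(rec))
        out = finalize_significance(
            rec, pool, p_raw, np.zeros(len(rec)), np.ones(len(rec)), set()
        )
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(p_raw * max(len(pool), 1), 1.0)
        )

    def test_matches_independent_oracle_on_synthetic_run(self):
        """Significance flags equal an independently coded chain of
        pool/z/tail/Bonferroni/gate decisions."""
        m, s, _ = simulate_dataset(
            SimConfig(
                n_genes=120,
                n_per_group=(6, 6, 6),
                planted={"I": (10, (2.0, 3.0)), "III": (10, (2.0, 3.0))},
                baseline_mean_range=(100.0, 1000.0),
                seed=31,
            )
        )
        cfg = DEConfig()
        mf = filter_low_expression(m, cfg, smallest_group=6)
        deg_a = differential_expression(mf, s, "autoimmune", cfg)
        deg_c = differential_expression(mf, s, "cancer", cfg)
        rec, pool = run_iit(deg_a, deg_c)
        null = build_null(mf, s, n_perm=20, seed=31, cfg=cfg)
        orig = rec["iit_score"].to_numpy()
        p_raw = pooled_pvalues(orig, null)
        counts = frequency_counts(null, orig)
        gated, freq_p = frequency_gate(null.gene_ids, counts, 0.05)
        got = finalize_significance(rec, pool, p_raw, counts, freq_p, gated)

        # oracle: plain numpy, no package calls
        pool_vec = np.concatenate([null.scores.ravel(), orig])
        z = (orig - pool_vec.mean()) / pool_vec.std()
        p_oracle = stats.norm.sf(z)
        sig_oracle = []
        for g, p in zip(rec["gene_id"], p_oracle):
            ok = g in pool and min(p * len(pool), 1.0) < 0.05 and g not in gated
            sig_oracle.append(ok)
        np.testing.assert_allclose(got["p_raw"], p_oracle, atol=1e-12)
        assert list(got["significant"]) == sig_oracle


class TestCutoff:
    def test_empirical_cutoff_matches_definition(self):
        rng = np.random.default_rng(9)
        scores = np.abs(rng.normal(size=(40, 50)))
        null = NullDistribution(50, tuple(f"g{i}" for i in range(40)), scores, 0)
        cut = significance_cutoff(null, threshold=0.05, method="empirical")
        pool = np.sort(scores.ravel())
        above = (pool > cut).sum()
        # scores above the cutoff satisfy (1 + #{>= s}) / (1 + N) < 0.05
        assert (1 + above) / (1 + len(pool)) < 0.05
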