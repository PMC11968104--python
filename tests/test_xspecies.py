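"""Orthologue mapping rules, hypergeometric overlap against exhaustive
enumeration, AUCell scores against their closed-form extremes and a
permutation expectation, and the two-sample t-test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vulnscan.xspecies import aucell_scores, enrichment_test, map_orthologs, overlap_stats


def _map(rows):
    return pd.DataFrame(rows, columns=["fly_gene", "human_gene", "score"])


class TestMapOrthologs:
    def test_score_threshold(self):
        m = _map([("a", "HA", 5), ("b", "HB", 4)])
        mapped, unmapped = map_orthologs(["a", "b"], m, min_score=5)
        assert mapped == ["HA"] and unmapped == 1

    def test_unmapped_counted(self):
        mapped, unmapped = map_orthologs(["nope"], _map([("a", "HA", 9)]))
        assert mapped == [] and unmapped == 1

    def test_best_score_then_lexicographic(self):
        m = _map([("a", "HA", 6), ("a", "HB", 9), ("b", "HC", 7), ("b", "HA", 7)])
        mapped, _ = map_orthologs(["a", "b"], m)
        assert mapped == ["HB", "HA"]  # best score wins; tie -> lexicographic


def exhaustive_hypergeom_upper(N, K, n, k):
    universe = range(N)
    flagged = set(range(K))
    count = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        count += len(flagged & set(draw)) >= k
    return count / total


class TestOverlapStats:
    def test_example_six_over_252(self):
        uni = [f"u{i}" for i in range(10)]
        res = overlap_stats(uni[:5], uni[1:5], uni)
        assert res.k == 4 and res.n == 5 and res.K == 4
        assert res.p_upper == pytest.approx(6 / 252)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 4, 5), (12, 6, 3)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        uni = [f"u{i}" for i in range(N)]
        b = uni[:K]
        for k in range(0, min(K, n) + 1):
            a = uni[:k] + uni[K : K + n - k]
            res = overlap_stats(a, b, uni)
            assert res.k == k
            assert res.p_upper == pytest.approx(exhaustive_hypergeom_upper(N, K, n, k), abs=1e-12)

    def test_p_monotone_in_k(self):
        uni = [f"u{i}" for i in range(20)]
        ps = []
        for k in range(0, 6):
            a = uni[:k] + uni[8 : 8 + 6 - k]
            ps.append(overlap_stats(a, uni[:8], uni).p_upper)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_degenerate_cases(self):
        uni = list("abcdef")
        empty = overlap_stats([], uni[:2], uni)
        assert empty.fraction is None and empty.p_upper is None
        full = overlap_stats(uni, uni, uni)
        assert full.fraction == 1.0 and full.p_upper == pytest.approx(1.0)
        zero = overlap_stats(uni[:3], uni[3:], uni)
        assert zero.k == 0 and zero.p_upper == pytest.approx(1.0)
        with pytest.raises(ValueError):
            overlap_stats(["zzz"], uni[:2], uni)


def test_planted_overlap_construction_recovered():
    """A human DEG list built so 30% of it consists of orthologues of the fly
    tail genes yields an overlap fraction of exactly 30%."""
    fly_tails = [f"f{i}" for i in range(100)]
    omap = _map([(f, f"H{f}", 9) for f in fly_tails])
    mapped, _ = map_orthologs(fly_tails, omap, min_score=5)
    rest = [f"Hx{i}" for i in range(70)]
    human_deg = mapped[:30] + rest
    background = [f"Hbg{i}" for i in range(800)]  # testable but unflagged genes
    universe = sorted(set(mapped) | set(rest) | set(background))
    res = overlap_stats(human_deg, mapped, universe)
    assert res.fraction == pytest.approx(0.30)
    assert res.p_upper < 1e-6


class TestAUCell:
    def test_set_at_top_scores_one(self):
        genes = [f"g{i}" for i in range(100)]
        expr = np.arange(100, 0, -1, dtype=float)[None, :]
        assert aucell_scores(expr, genes, genes[:3], top_fraction=0.1)[0] == pytest.approx(1.0)

    def test_set_outside_window_scores_zero(self):
        genes = [f"g{i}" for i in range(100)]
        expr = np.arange(100, 0, -1, dtype=float)[None, :]
        assert aucell_scores(expr, genes, genes[-3:], top_fraction=0.1)[0] == 0.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        expr = rng.lognormal(size=(5, 200))
        s1 = aucell_scores(expr, genes, genes[::7], seed=0)
        s2 = aucell_scores(np.log1p(expr) ** 3, genes, genes[::7], seed=0)
        np.testing.assert_allclose(s1, s2)

    def test_random_set_matches_permutation_expectation(self):
        rng = np.random.default_rng(4)
        n_genes, n_cells = 2000, 500
        genes = [f"g{i}" for i in range(n_genes)]
        gene_set = list(rng.choice(genes, 50, replace=False))
        expr = rng.normal(size=(n_cells, n_genes))
        scores = aucell_scores(expr, genes, gene_set, top_fraction=0.05, seed=1)
        # permutation oracle: average AUC of uniformly random rankings
        perm_rng = np.random.default_rng(7)
        window = math.ceil(0.05 * n_genes)
        m = 50
        max_auc = sum(min(i, m) for i in range(1, window + 1))
        sims = []
        for _ in range(3000):
            ranks = perm_rng.choice(n_genes, m, replace=False) + 1
            hits = ranks[ranks <= window]
            sims.append((window - hits + 1).sum() / max_auc)
        expected = np.mean(sims)
        se = scores.std(ddof=1) / np.sqrt(n_cells)
        assert abs(scores.mean() - expected) < 3 * se + 3 * np.std(sims, ddof=1) / np.sqrt(3000)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            aucell_scores(np.ones((2, 3)), ["a", "b", "c"], ["zzz"])


class TestEnrichmentTest:
    def test_identical_groups(self):
        t, p = enrichment_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p = enrichment_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_swap_antisymmetry(self):
        t1, p1 = enrichment_test([1, 2, 3], [4, 5, 6])
        t2, p2 = enrichment_test([4, 5, 6], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_equal_means(self):
        t, p = enrichment_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
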