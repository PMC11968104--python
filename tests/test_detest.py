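"""Differential-expression routes checked against independent oracles:
exhaustive permutation for the rank-sum p, a hand-rolled BH step-up, and
planted synthetic truth for sign and recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from vulnscan import detest, preprocess, synthgen
from vulnscan.detest import (
    ClusterSkippedWarning,
    Pseudobulk,
    _ranksum_table,
    downsample_cluster,
    make_pseudobulks,
    method_concordance,
    pseudobulk_de,
    ranksum_de,
    signed_significance,
)


def exact_ranksum_p(x, y):
    """Exhaustive two-sided rank-sum p: enumerate every assignment of the
    pooled values to the two groups and count U statistics at least as
    extreme (in either tail) as observed."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += (u <= lo) or (u >= hi)
        total += 1
    return count / total


def bh_stepup(p):
    """Reference Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 5, 2], [3, 9, 4]),
        ([10, 2, 7, 1], [3, 8, 6]),
        ([1.5, 2.5], [0.5, 3.5, 4.5]),
        ([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12]),
    ],
)
def test_ranksum_matches_exhaustive_permutation_oracle(x, y):
    table = _ranksum_table(np.array(x)[:, None], np.array(y)[:, None], np.array(["g"]))
    assert table["p"].iloc[0] == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)


def test_ranksum_example_point_one():
    table = _ranksum_table(
        np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]), np.array(["g"])
    )
    assert table["p"].iloc[0] == pytest.approx(0.1)


def test_identical_groups_give_p_one_lfc_zero():
    A = np.tile([1.0, 2.0, 3.0], (4, 1)).T[:, :2]
    table = _ranksum_table(A, A.copy(), np.array(["a", "b"]))
    assert (table["p"] == 1.0).all()
    assert (table["lfc"] == 0.0).all()


def test_ranksum_skips_tiny_arms(small_cohort_lognorm):
    adata, _, _ = small_cohort_lognorm
    sub = adata[adata.obs.index[:10]].copy()
    sub.obs["cluster"] = "solo"
    with pytest.warns(ClusterSkippedWarning):
        assert ranksum_de(sub, "solo", "mut1") is None


def test_bh_adjustment_matches_reference(rng):
    p = rng.uniform(size=200)
    table = _ranksum_table(
        rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), np.array(["a", "b", "c"])
    )
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))
    np.testing.assert_allclose(table["p_adj"], bh_stepup(table["p"]))


def test_make_pseudobulks_thresholds_and_conservation(small_cohort):
    adata, _, _ = small_cohort
    import anndata as ad
    import scipy.sparse as sp

    counts = np.arange(1, 32 * 3 + 1).reshape(32, 3)
    obs = pd.DataFrame(
        {
            "genotype": ["m"] * 32,
            "run": ["r1"] * 12 + ["r2"] * 10 + ["r3"] * 9 + ["r4"],
            "cluster": ["0"] * 32,
        },
        index=[f"c{i}" for i in range(32)],
    )
    toy = ad.AnnData(X=sp.csr_matrix(counts), obs=obs)
    pbs = make_pseudobulks(toy, "0")
    assert [(p.run_id, p.n_cells) for p in pbs] == [("r1", 12), ("r2", 10)]
    np.testing.assert_array_equal(pbs[0].counts, counts[:12].sum(axis=0))
    # one cell per run -> nothing retained
    toy.obs["run"] = [f"r{i}" for i in range(32)]
    assert make_pseudobulks(toy, "0") == []


def _nb_pseudobulks(rng, mu, alpha, n_per_arm=4, lfc=None):
    pbs = []
    for arm, genotype in ((0, "mut"), (1, "control")):
        m = mu * (2.0**lfc if (lfc is not None and arm == 0) else 1.0)
        for i in range(n_per_arm):
            counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * m)).astype(float)
            pbs.append(Pseudobulk(f"{genotype}_r{i}", genotype, "0", counts, 50))
    return pbs


def test_pseudobulk_constant_gene_gives_null_result(rng):
    counts = np.full(5, 40.0)
    pbs = [
        Pseudobulk(f"r{i}", "mut" if i < 3 else "control", "0", np.array([40.0, 40.0]), 20)
        for i in range(6)
    ]
    table = pseudobulk_de(pbs, "mut")
    assert table["lfc"].iloc[0] == pytest.approx(0.0, abs=1e-8)
    assert table["p"].iloc[0] > 0.99
    del counts


def test_pseudobulk_skips_single_pseudobulk_arm(rng):
    pbs = _nb_pseudobulks(rng, np.array([20.0]), 0.3)[0:1] + _nb_pseudobulks(
        rng, np.array([20.0]), 0.3
    )[4:]
    with pytest.warns(ClusterSkippedWarning):
        assert pseudobulk_de(pbs, "mut") is None


def test_pseudobulk_sign_recovery(rng):
    """Fitted coefficient sign matches the planted sign for >=95% of genes."""
    mu = rng.lognormal(3.5, 0.8, 200)
    signs = rng.choice([-1.0, 1.0], 200)
    pbs = []
    for genotype in ("mut", "control"):
        m = mu * np.exp2(signs) if genotype == "mut" else mu
        for i in range(4):
            counts = rng.negative_binomial(1 / 0.2, 1 / (1 + 0.2 * m)).astype(float)
            pbs.append(Pseudobulk(f"{genotype}{i}", genotype, "0", counts, 50))
    table = pseudobulk_de(pbs, "mut")
    agree = np.sign(table["lfc"]) == signs
    assert agree.mean() >= 0.95


def test_signed_significance_arithmetic():
    table = pd.DataFrame(
        {
            "gene": ["up", "null", "down", "floor"],
            "lfc": [2.0, 0.0, -1.5, 1.0],
            "p": [1e-4, 0.5, 1e-2, 0.0],
            "p_adj": [1.0] * 4,
            "method": "ranksum",
        }
    )
    s = signed_significance(table)
    assert s["up"] == pytest.approx(8.0)
    assert s["null"] == 0.0
    assert s["down"] == pytest.approx(-3.0)
    assert np.isfinite(s["floor"]) and s["floor"] == pytest.approx(300.0)


def test_method_concordance_limits_and_example():
    t = pd.DataFrame(
        {
            "gene": list("abcd"),
            "lfc": [1.0, 1.0, 1.0, 1.0],
            "p": [10 ** -v for v in [1.0, 2.0, 3.0, 4.0]],
            "p_adj": [1.0] * 4,
            "method": "ranksum",
        }
    )
    assert method_concordance(t, t) == pytest.approx(1.0)
    flipped = t.assign(lfc=-t["lfc"])
    assert method_concordance(t, flipped) == pytest.approx(-1.0)
    # scores A=[1,2,3,4] vs B=[1,3,2,4] -> Spearman 0.8
    t_b = t.copy()
    t_b["p"] = [10 ** -v for v in [1.0, 3.0, 2.0, 4.0]]
    assert method_concordance(t, t_b) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        method_concordance(t.iloc[:2], t.iloc[2:])


def test_downsample_cluster_seeded_and_identity(small_cohort):
    adata, _, _ = small_cohort
    cluster = "2"
    arm_sizes = adata.obs.loc[adata.obs["cluster"] == cluster].groupby("genotype", observed=True).size()
    n = int(arm_sizes.min())
    full = downsample_cluster(adata, cluster, n=n, seed=1)
    a = downsample_cluster(adata, cluster, 10, seed=5)
    b = downsample_cluster(adata, cluster, 10, seed=5)
    assert list(a.obs.index) == list(b.obs.index)
    in_cluster = full.obs["cluster"] == cluster
    assert (full.obs.loc[in_cluster].groupby("genotype", observed=True).size() <= n).all()
    with pytest.raises(ValueError):
        downsample_cluster(adata, cluster, n=10**6)


def test_ndeg_monotone_in_downsampling_depth():
    """Mean DEG count grows with cells retained per arm on planted data."""
    cfg = synthgen.CohortConfig(
        n_genotypes=1, n_clusters=1, cluster_size_median=200, cluster_size_sigma=0.05,
        n_genes=300, vulnerable_clusters=(0,), n_deg_per_vulnerable=40,
        lfc_magnitude=1.5, seed=21,
    )
    adata, _ = synthgen.generate_cohort(cfg)
    adata = preprocess.log_normalize(adata)
    means = []
    for n in (20, 60, 150):
        ndeg = []
        for seed in range(5):
            sub = downsample_cluster(adata, "0", n=n, seed=seed)
            table = ranksum_de(sub, "0", "mut1")
            ndeg.append(detest.count_deg(table))
        means.append(np.mean(ndeg))
    assert means[0] <= means[1] <= means[2]
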