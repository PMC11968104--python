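"""The generator must be deterministic, honor its no-effect limit, and
produce over-dispersed counts whose null p-values are uniform."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from vulnscan import detest, preprocess, synthgen


def _tiny_config(**kw):
    base = dict(
        n_genotypes=2,
        n_clusters=4,
        cluster_size_median=40,
        n_genes=200,
        vulnerable_clusters=(0,),
        n_deg_per_vulnerable=20,
        seed=7,
    )
    base.update(kw)
    return synthgen.CohortConfig(**base)


def test_seed_determinism():
    a1, t1 = synthgen.generate_cohort(_tiny_config())
    a2, t2 = synthgen.generate_cohort(_tiny_config())
    assert (sp.csr_matrix(a1.X) != sp.csr_matrix(a2.X)).nnz == 0
    assert a1.obs.equals(a2.obs)
    assert t1.to_dict() == t2.to_dict()
    a3, _ = synthgen.generate_cohort(_tiny_config(seed=8))
    assert a1.shape != a3.shape or (sp.csr_matrix(a1.X) != sp.csr_matrix(a3.X)).nnz != 0


def test_no_effect_case_has_empty_truth_and_equal_means():
    cfg = _tiny_config(n_deg_per_vulnerable=0, cluster_size_median=400, n_genes=100)
    adata, truth = synthgen.generate_cohort(cfg)
    assert truth.shared_up == [] and truth.shared_down == []
    assert all(not v for v in truth.planted_deg.values())
    X = sp.csr_matrix(adata.X)
    mask_c = (adata.obs["genotype"] == "control").to_numpy()
    mask_m = (adata.obs["genotype"] == "mut1").to_numpy()
    mean_c = np.asarray(X[mask_c].mean(axis=0)).ravel()
    mean_m = np.asarray(X[mask_m].mean(axis=0)).ravel()
    # same generative mean per gene up to cluster modulation; compare pooled
    # means with a generous sampling tolerance
    assert np.corrcoef(mean_c, mean_m)[0, 1] > 0.95


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        _tiny_config(shared_fraction=1.5).validate()
    with pytest.raises(ValueError):
        _tiny_config(vulnerable_clusters=(99,)).validate()
    with pytest.raises(ValueError):
        _tiny_config(baseline_nb_dispersion=-1).validate()


def test_truth_shared_sets_subset_of_every_genotype():
    adata, truth, cfg = None, None, None
    adata, truth = synthgen.generate_cohort(_tiny_config(n_genotypes=3))
    shared = set(truth.shared_up) | set(truth.shared_down)
    for genotype, clusters in truth.planted_deg.items():
        for cluster, genes in clusters.items():
            assert shared <= set(genes)


def test_overdispersion_exceeds_poisson():
    """Method-of-moments: marginal variance > mean when alpha > 0."""
    cfg = _tiny_config(
        n_genotypes=1, n_clusters=1, cluster_size_median=2000, n_genes=300,
        vulnerable_clusters=(), n_deg_per_vulnerable=0, baseline_nb_dispersion=1.0,
    )
    adata, _ = synthgen.generate_cohort(cfg)
    X = np.asarray(sp.csr_matrix(adata.X)[(adata.obs["genotype"] == "control").to_numpy()].todense())
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    strong = mean > 0.5
    assert (var[strong] > mean[strong]).mean() > 0.9


def test_null_pvalues_uniform():
    """With no planted effects, rank-sum p-values are uniform (KS test)."""
    cfg = synthgen.CohortConfig(
        n_genotypes=1, n_clusters=1, cluster_size_median=150, cluster_size_sigma=0.0,
        n_genes=10_000, vulnerable_clusters=(), n_deg_per_vulnerable=0, seed=5,
    )
    adata, _ = synthgen.generate_cohort(cfg)
    adata = preprocess.log_normalize(adata)
    table = detest.ranksum_de(adata, "0", "mut1")
    # discard genes that are all-zero in both arms (point mass at p=1)
    expressed = table["p"] < 1
    p = table.loc[expressed, "p"]
    stat, ks_p = scipy.stats.kstest(p, "uniform")
    assert ks_p > 0.01


def test_planted_deg_recovered_by_ranksum(small_cohort_lognorm):
    """Rank-sum DE on a vulnerable cluster recovers >=80% of planted genes."""
    adata, truth, cfg = small_cohort_lognorm
    cfg_big = synthgen.CohortConfig(
        n_genotypes=1, n_clusters=2, cluster_size_median=250, cluster_size_sigma=0.1,
        n_genes=500, vulnerable_clusters=(0, 1), n_deg_per_vulnerable=25,
        lfc_magnitude=2.0, seed=3,
    )
    big, big_truth = synthgen.generate_cohort(cfg_big)
    big = preprocess.log_normalize(big)
    table = detest.ranksum_de(big, "0", "mut1")
    planted = set(big_truth.planted_deg["mut1"]["0"])
    hits = set(table.loc[table["p_adj"] < 0.05, "gene"]) & planted
    assert len(hits) / len(planted) >= 0.8


def test_bulk_references_zero_noise_equal_cluster_means(small_cohort):
    adata, _, _ = small_cohort
    panel = synthgen.generate_bulk_references(adata, noise_sd=0.0, seed=1)
    X = sp.csr_matrix(adata.X)
    c = sorted(adata.obs["cluster"].unique())[0]
    mask = (adata.obs["cluster"] == c).to_numpy()
    np.testing.assert_allclose(
        panel[f"ref_{c}"].to_numpy(), np.asarray(X[mask].mean(axis=0)).ravel()
    )
    p2 = synthgen.generate_bulk_references(adata, noise_sd=0.3, seed=9)
    p3 = synthgen.generate_bulk_references(adata, noise_sd=0.3, seed=9)
    assert p2.equals(p3)


def test_ortholog_map_score_range_and_determinism():
    m = synthgen.generate_ortholog_map(["a", "b", "c"], ["X", "Y"], score_range=(5, 5), seed=0)
    assert (m["score"] == 5).all()
    m2 = synthgen.generate_ortholog_map(["a", "b", "c"], ["X", "Y"], score_range=(5, 5), seed=0)
    assert m.equals(m2)
    with pytest.raises(ValueError):
        synthgen.generate_ortholog_map(["a"], ["X"], score_range=(6, 5))
    with pytest.raises(ValueError):
        synthgen.generate_ortholog_map([], ["X"])


def test_traces_constant_and_single_spike():
    ts, truth = synthgen.generate_traces(2, n_frames=120, baseline=4.0, noise_sd=0.0)
    assert np.all(ts.F == 4.0)
    assert truth["active_fraction"] == 0.0
    ts2, truth2 = synthgen.generate_traces(
        1, n_frames=120, baseline=10.0, spike_times=[100], spike_amp=5.0, stimulus_frame=50
    )
    from vulnscan import phenoscores

    dff = phenoscores.dff_trace(ts2, "prestim_mean5")
    assert dff[100, 0] == pytest.approx(0.5)
    assert truth2["active_fraction"] == pytest.approx(1 / 120)
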