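"""Find cell types with more differential genes than their size predicts.

Generates a synthetic multi-genotype cohort with two planted vulnerable
clusters, runs per-cluster rank-sum differential expression for each mutant
against the control, fits the negative-binomial DEG-count-vs-size model, and
prints the consensus vulnerability ranking. The planted clusters (0 and 1)
should top the list with large positive residuals.
"""

from vulnscan import detest, preprocess, synthgen, vulnmodel

cfg = synthgen.CohortConfig(
    n_genotypes=3,
    n_clusters=12,
    cluster_size_median=60,
    n_genes=400,
    vulnerable_clusters=(0, 1),
    n_deg_per_vulnerable=50,
    lfc_magnitude=2.0,
    background_deg=60,
    background_lfc=1.0,
    seed=1,
)
adata, truth = synthgen.generate_cohort(cfg)
adata = preprocess.log_normalize(adata)
print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, planted vulnerable: {truth.vulnerable_clusters}")

residuals = {}
for mutant in ("mut1", "mut2", "mut3"):
    stats = []
    for cluster in sorted(adata.obs["cluster"].unique()):
        table = detest.ranksum_de(adata, cluster, mutant)
        if table is None:
            continue
        mask = (adata.obs["cluster"] == cluster).to_numpy()
        stats.append(
            vulnmodel.ClusterStats(
                cluster=cluster,
                y=detest.count_deg(table),  # genes at adjusted p < 0.05
                x1=int((mask & (adata.obs["genotype"] == mutant).to_numpy()).sum()),
                x2=int((mask & (adata.obs["genotype"] == "control").to_numpy()).sum()),
            )
        )
    fit = vulnmodel.fit_nb_model(stats)
    print(f"{mutant}: log(mu) = {fit.intercept:.2f} + {fit.b1:.2f} * log(min cells), alpha = {fit.alpha:.2f}")
    residuals[mutant] = vulnmodel.cluster_residuals(fit, stats)

consensus = vulnmodel.rank_vulnerable(residuals, top_k=2)
print("\nconsensus ranking (top = commonly affected beyond size expectation):")
print(consensus.head(5).to_string(index=False))
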