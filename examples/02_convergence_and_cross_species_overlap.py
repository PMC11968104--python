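"""Aggregate signed DE evidence across genotypes and test the cross-species
overlap of the common tails.

Three mutants share a set of planted up/down genes in one vulnerable cluster.
Gene ranks by signed significance are summed across mutants; the top and
bottom 5% form the common up/down sets. Those are mapped through a synthetic
orthologue map (confidence >= 5) and intersected with a synthetic "human DEG"
list built to contain 30% of the shared genes' orthologues — the printed
overlap fraction should land near 0.3, with a small hypergeometric p.
"""

import numpy as np

from vulnscan import convergence, detest, preprocess, synthgen, xspecies

cfg = synthgen.CohortConfig(
    n_genotypes=3,
    n_clusters=1,
    cluster_size_median=180,
    cluster_size_sigma=0.1,
    n_genes=2000,
    vulnerable_clusters=(0,),
    n_deg_per_vulnerable=150,
    lfc_magnitude=2.0,
    shared_fraction=0.6,
    seed=2,
)
adata, truth = synthgen.generate_cohort(cfg)
adata = preprocess.log_normalize(adata)

tables = {m: detest.ranksum_de(adata, "0", m) for m in ("mut1", "mut2", "mut3")}
result = convergence.converge(tables, tail_fraction=0.05)
up_recovered = len(set(truth.shared_up) & set(result.common_up)) / len(truth.shared_up)
print(f"common_up: {len(result.common_up)} genes, {100 * up_recovered:.0f}% of planted shared-up recovered")

# cross-species: orthologue map + synthetic human DEG list with planted overlap
human_genes = [f"HS{i:05d}" for i in range(2000)]
omap = synthgen.generate_ortholog_map(list(adata.var_names), human_genes, score_range=(1, 15), seed=3)
fly_tails_mapped, n_unmapped = xspecies.map_orthologs(
    result.common_up + result.common_down, omap, min_score=5
)
print(f"fly tail genes mapped to human: {len(fly_tails_mapped)} ({n_unmapped} unmapped/low-score)")

rng = np.random.default_rng(4)
shared_mapped, _ = xspecies.map_orthologs(truth.shared_up + truth.shared_down, omap, min_score=5)
n_keep = int(round(0.3 * len(shared_mapped)))
extras = [g for g in rng.permutation(human_genes) if g not in set(shared_mapped)][: 2 * n_keep]
human_deg = shared_mapped[:n_keep] + extras

mappable, _ = xspecies.map_orthologs(sorted(set(omap["fly_gene"])), omap, min_score=5)
universe = sorted(set(mappable) | set(human_deg))
res = xspecies.overlap_stats(set(human_deg) & set(universe), set(fly_tails_mapped), universe)
print(
    f"overlap: {res.k}/{res.n} = {100 * res.fraction:.1f}% of human DEG orthologues "
    f"in the fly common tails (universe {res.N}, hypergeometric p = {res.p_upper:.2e})"
)
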