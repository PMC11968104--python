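"""How many cells must be sequenced to recover the cell types of a tissue?

Subsamples a labeled population (cluster labels of a synthetic cohort) at
increasing sizes, counts the cell types detected (>= threshold cells drawn),
and fits Michaelis-Menten kinetics: Vmax is the asymptotic number of
detectable types and Km the cell count at half-saturation. A common rule of
thumb is that ~4-5x Km cells recover ~80% of Vmax.
"""

from vulnscan import saturation, synthgen

cfg = synthgen.CohortConfig(
    n_genotypes=2,
    n_clusters=25,
    cluster_size_median=120,
    cluster_size_sigma=0.8,  # realistic mix of abundant and rare types
    n_genes=100,
    vulnerable_clusters=(),
    n_deg_per_vulnerable=0,
    seed=7,
)
adata, _ = synthgen.generate_cohort(cfg)
labels = adata.obs["cluster"].tolist()
print(f"population: {len(labels)} cells, {len(set(labels))} cell types")

for threshold in (1, 5, 10):
    curve = saturation.subsample_curve(
        labels, max_n=4000, step=100, reps=50, threshold=threshold, seed=8
    )
    fit = saturation.fit_michaelis_menten(curve)
    print(
        f"threshold {threshold:>2} cells: Vmax = {fit.vmax:5.1f} types, "
        f"Km = {fit.km:7.0f} cells (half the types seen by {fit.km:.0f} sampled cells)"
    )
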