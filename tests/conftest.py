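import numpy as np
import pytest

from vulnscan import preprocess, synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by recovery tests: 3 mutants + control,
    8 clusters (2 vulnerable, lfc=2), 400 genes."""
    cfg = synthgen.CohortConfig(
        n_genotypes=3,
        n_clusters=8,
        cluster_size_median=60,
        cluster_size_sigma=0.3,
        n_genes=400,
        vulnerable_clusters=(0, 1),
        n_deg_per_vulnerable=40,
        lfc_magnitude=2.0,
        shared_fraction=0.5,
        seed=42,
    )
    adata, truth = synthgen.generate_cohort(cfg)
    return adata, truth, cfg


@pytest.fixture(scope="session")
def small_cohort_lognorm(small_cohort):
    adata, truth, cfg = small_cohort
    return preprocess.log_normalize(adata), truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
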