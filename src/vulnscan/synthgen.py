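"""Seeded synthetic cohorts with the structure the downstream analysis assumes.

The generator emulates a multi-genotype brain scRNA-seq study: several mutant
genotypes plus one ``"control"``, cells grouped into clusters of log-normally
distributed sizes, negative-binomially distributed counts, per-run batch
labels, and a mitochondrial gene subset. A chosen set of *vulnerable* clusters
carries planted differentially expressed genes in the mutant genotypes only,
a configurable fraction of which is shared across all mutants — the signal the
convergence analysis is meant to recover. Companion generators produce bulk
reference panels (cluster means plus multiplicative noise), orthologue maps
with integer confidence scores, and fluorescence traces with planted spikes.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .phenoscores import TraceSet

CONTROL = "control"


@dataclass
class CohortConfig:
    """Parameters of a synthetic multi-genotype cohort.

    Defaults describe a desk-scale analogue of a whole-brain atlas cohort:
    five mutant genotypes against a shared control, log-normal cluster sizes,
    sparse over-dispersed counts (baseline gene means log-normal with median
    0.5 counts/cell), and a handful of vulnerable clusters carrying planted
    log2 fold changes. ``background_deg`` optionally plants mild genotype-wide
    deregulation in every cluster of a mutant (``background_lfc`` magnitude,
    random signs), giving null clusters a DEG count that grows with cluster
    size; it defaults to 0 so the no-effect limits hold exactly.
    """

    n_genotypes: int = 5
    n_clusters: int = 20
    cluster_size_median: float = 200.0
    cluster_size_sigma: float = 0.4
    n_genes: int = 2000
    mito_fraction: float = 0.05
    n_runs_per_genotype: int = 4
    vulnerable_clusters: tuple = (0, 1, 2)
    n_deg_per_vulnerable: int = 100
    lfc_magnitude: float = 1.0
    shared_fraction: float = 0.5
    baseline_nb_dispersion: float = 0.5
    gene_mean_median: float = 0.5
    gene_mean_sigma: float = 1.0
    cluster_mod_sigma: float = 0.5
    background_deg: int = 0
    background_lfc: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genotypes", "n_clusters", "n_genes", "n_runs_per_genotype"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mito_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.baseline_nb_dispersion < 0:
            raise ValueError("baseline_nb_dispersion must be >= 0")
        if self.n_deg_per_vulnerable < 0:
            raise ValueError("n_deg_per_vulnerable must be >= 0")
        bad = [c for c in self.vulnerable_clusters if not 0 <= int(c) < self.n_clusters]
        if bad:
            raise ValueError(f"vulnerable_clusters outside cluster range: {bad}")
        if self.n_deg_per_vulnerable > self.n_genes:
            raise ValueError("n_deg_per_vulnerable exceeds n_genes")
        if self.background_deg < 0 or self.background_deg > self.n_genes:
            raise ValueError("background_deg must lie in [0, n_genes]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``planted_deg`` maps genotype -> cluster id -> {gene: signed log2 fold
    change}. ``shared_up`` / ``shared_down`` are the genes planted with the
    same sign in every mutant genotype's vulnerable clusters.
    """

    planted_deg: dict = field(default_factory=dict)
    shared_up: list = field(default_factory=list)
    shared_down: list = field(default_factory=list)
    vulnerable_clusters: list = field(default_factory=list)
    background_deg: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_deg": self.planted_deg,
            "shared_up": list(self.shared_up),
            "shared_down": list(self.shared_down),
            "vulnerable_clusters": list(self.vulnerable_clusters),
            "background_deg": self.background_deg,
        }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Draw counts with E=mean and Var=mean + alpha*mean^2 (Poisson at alpha=0)."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_cohort(config: CohortConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a cohort of NB counts with planted DEGs in vulnerable clusters.

    Returns the cell x gene count matrix (AnnData with obs columns genotype,
    run, cluster and var column mito) and the ground-truth record. Control
    cells carry no planted effects; mutant cells in vulnerable clusters have
    planted gene means multiplied by ``2**(+/- lfc_magnitude)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    n_mito = int(round(config.mito_fraction * n_genes))
    mito = np.zeros(n_genes, dtype=bool)
    mito[:n_mito] = True
    symbols = np.where(mito, np.char.add("mt:", genes), genes)

    # Baseline expression: log-normal around a sparse-brain regime, plus a
    # per-cluster modulation so cluster profiles are mutually distinguishable.
    base_mean = rng.lognormal(np.log(config.gene_mean_median), config.gene_mean_sigma, n_genes)
    cluster_mod = rng.lognormal(0.0, config.cluster_mod_sigma, (config.n_clusters, n_genes))

    genotypes = [CONTROL] + [f"mut{i + 1}" for i in range(config.n_genotypes)]
    vulnerable = [int(c) for c in config.vulnerable_clusters]

    # Plant DEGs: one shared set (same gene, same sign in every mutant) and a
    # genotype-private remainder, both confined to the vulnerable clusters.
    truth = SyntheticTruth(vulnerable_clusters=[str(c) for c in vulnerable])
    n_deg = config.n_deg_per_vulnerable
    n_shared = int(round(config.shared_fraction * n_deg))
    planted: dict[str, dict[str, dict[str, float]]] = {g: {} for g in genotypes[1:]}
    shared_genes: np.ndarray = np.array([], dtype=int)
    shared_sign: np.ndarray = np.array([], dtype=float)
    if n_deg > 0 and vulnerable:
        order = rng.permutation(n_genes)
        shared_genes = order[:n_shared]
        shared_sign = rng.choice([-1.0, 1.0], size=n_shared)
        pool = order[n_shared:]
        n_private = n_deg - n_shared
        offset = 0
        for g in genotypes[1:]:
            if (offset + n_private) > len(pool):
                raise ValueError("not enough genes to plant disjoint private DEG sets")
            private = pool[offset : offset + n_private]
            offset += n_private
            private_sign = rng.choice([-1.0, 1.0], size=n_private)
            idx = np.concatenate([shared_genes, private])
            sign = np.concatenate([shared_sign, private_sign])
            lfc = sign * config.lfc_magnitude
            for c in vulnerable:
                planted[g][str(c)] = {genes[i]: float(f) for i, f in zip(idx, lfc)}
        truth.shared_up = sorted(genes[shared_genes[shared_sign > 0]])
        truth.shared_down = sorted(genes[shared_genes[shared_sign < 0]])
    truth.planted_deg = planted

    # Mild genotype-wide background deregulation (every cluster of a mutant):
    # gives null clusters a DEG count that grows with cluster size, the
    # regime the DEG-count-vs-size model is designed for.
    background: dict[str, dict[int, float]] = {}
    if config.background_deg > 0:
        for g in genotypes[1:]:
            idx = rng.choice(n_genes, size=config.background_deg, replace=False)
            sign = rng.choice([-1.0, 1.0], size=config.background_deg)
            background[g] = {int(i): float(s * config.background_lfc) for i, s in zip(idx, sign)}
            truth.background_deg[g] = {genes[i]: f for i, f in background[g].items()}

    blocks, obs_rows = [], []
    cell_counter = 0
    for g in genotypes:
        for c in range(config.n_clusters):
            size = int(round(rng.lognormal(np.log(config.cluster_size_median), config.cluster_size_sigma)))
            if size < 1:
                raise ValueError(f"empty cluster after size draw: genotype={g} cluster={c}")
            mean = base_mean * cluster_mod[c]
            if g in background:
                mean = mean.copy()
                bidx = np.fromiter(background[g].keys(), dtype=int)
                blfc = np.fromiter(background[g].values(), dtype=float)
                mean[bidx] = mean[bidx] * np.exp2(blfc)
            if g != CONTROL and str(c) in planted.get(g, {}):
                mean = mean.copy()
                eff = planted[g][str(c)]
                idx = np.array([np.searchsorted(genes, k) for k in eff])
                lfc = np.array([eff[genes[i]] for i in idx])
                mean[idx] = mean[idx] * np.exp2(lfc)
            counts = _nb_draw(rng, np.broadcast_to(mean, (size, n_genes)), config.baseline_nb_dispersion)
            blocks.append(sp.csr_matrix(counts.astype(np.int32)))
            runs = [f"{g}_run{j % config.n_runs_per_genotype}" for j in range(size)]
            for j in range(size):
                obs_rows.append((f"cell{cell_counter + j:07d}", g, runs[j], str(c)))
            cell_counter += size

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "genotype", "run", "cluster"]).set_index("cell_id")
    var = pd.DataFrame({"symbol": symbols, "mito": mito}, index=genes)
    var.index.name = "gene"
    return ad.AnnData(X=X, obs=obs, var=var), truth


def generate_bulk_references(matrix: ad.AnnData, noise_sd: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """One bulk profile per cluster: cluster mean counts with multiplicative
    log-normal noise of scale ``noise_sd`` (``noise_sd=0`` returns the means).

    Returns a genes x profiles DataFrame with profile labels ``ref_<cluster>``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if "cluster" not in matrix.obs:
        raise ValueError("matrix lacks cluster labels")
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(matrix.X)
    profiles = {}
    for c in sorted(matrix.obs["cluster"].unique(), key=str):
        mask = (matrix.obs["cluster"] == c).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cluster {c} has 0 cells")
        mean = np.asarray(X[mask].mean(axis=0)).ravel()
        if noise_sd > 0:
            mean = mean * rng.lognormal(0.0, noise_sd, mean.shape)
        profiles[f"ref_{c}"] = mean
    return pd.DataFrame(profiles, index=matrix.var_names)


def generate_ortholog_map(
    fly_genes,
    human_genes,
    score_range: tuple[int, int] = (1, 15),
    seed: int = 0,
    p_unmapped: float = 0.2,
    max_pairs: int = 2,
) -> pd.DataFrame:
    """Random many-to-many orthologue map with integer confidence scores.

    Each fly gene maps to 0..``max_pairs`` human genes (none with probability
    ``p_unmapped``); scores are uniform integers in the inclusive
    ``score_range``. Returns a DataFrame with columns fly_gene, human_gene,
    score.
    """
    fly_genes, human_genes = list(fly_genes), list(human_genes)
    if not fly_genes or not human_genes:
        raise ValueError("gene lists must be nonempty")
    lo, hi = int(score_range[0]), int(score_range[1])
    if lo > hi:
        raise ValueError("empty score_range")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fly_genes:
        if rng.random() < p_unmapped:
            continue
        k = int(rng.integers(1, max_pairs + 1))
        partners = rng.choice(len(human_genes), size=min(k, len(human_genes)), replace=False)
        for h in partners:
            rows.append((f, human_genes[h], int(rng.integers(lo, hi + 1))))
    return pd.DataFrame(rows, columns=["fly_gene", "human_gene", "score"]).drop_duplicates()


def generate_traces(
    n_rois: int,
    frame_rate: float = 5.0,
    n_frames: int = 300,
    baseline: float = 10.0,
    spike_times=(),
    spike_amp: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    stimulus_frame: int | None = None,
) -> tuple[TraceSet, dict]:
    """Fluorescence traces = baseline + planted spikes + Gaussian noise.

    Returns the trace set (frames x ROIs) and a ground-truth dict with the
    planted spike frames and the active-frame fraction.
    """
    if n_rois <= 0:
        raise ValueError("n_rois must be > 0")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rng = np.random.default_rng(seed)
    F = np.full((n_frames, n_rois), float(baseline))
    spike_times = [int(t) for t in spike_times]
    for t in spike_times:
        if not 0 <= t < n_frames:
            raise ValueError(f"spike frame {t} outside trace")
        F[t, :] += spike_amp
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, F.shape)
    truth = {
        "spike_frames": spike_times,
        "active_fraction": len(set(spike_times)) / n_frames,
    }
    return TraceSet(F=F, frame_rate=frame_rate, stimulus_frame=stimulus_frame), truth
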