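"""Per-cluster mutant-vs-control differential expression by two routes.

Route 1 (``ranksum_de``) applies a two-sided Wilcoxon rank-sum test per gene
on normalized expression, cell against cell. Route 2 (``pseudobulk_de``)
first sums the raw counts of all cells sharing an experimental run into
pseudobulks (keeping only pseudobulks of >= 10 cells) and then fits, per
gene, a negative-binomial GLM with a log link, a genotype indicator and a
log-library-size offset — the bulk-style analysis re-expressed as an explicit
NB2 model with per-gene profile-likelihood dispersion.

The two routes are compared through *signed significance*, ``lfc x
(-log10 p)``, whose Spearman correlation across genes is the method
concordance statistic. ``downsample_cluster`` equalizes cluster sizes to
guard the downstream DEG-count model against pure size effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterSkippedWarning",
    "Pseudobulk",
    "ranksum_de",
    "make_pseudobulks",
    "pseudobulk_de",
    "signed_significance",
    "method_concordance",
    "downsample_cluster",
    "count_deg",
]

MIN_PSEUDOBULK_CELLS = 10
P_FLOOR = 1e-300


class ClusterSkippedWarning(UserWarning):
    """A contrast could not be tested (too few cells or pseudobulks)."""


@dataclass
class Pseudobulk:
    """Summed gene counts of all cells sharing one experimental run."""

    run_id: str
    genotype: str
    cluster: str
    counts: np.ndarray
    n_cells: int
    genes: np.ndarray | None = None


def _expression(adata: ad.AnnData) -> sp.csr_matrix:
    """Normalized expression for cell-level testing (lognorm layer if present)."""
    if "lognorm" in adata.layers:
        return sp.csr_matrix(adata.layers["lognorm"])
    return sp.csr_matrix(adata.X, dtype=float)


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    """Raw counts for pseudobulking (counts layer if present)."""
    if "counts" in adata.layers:
        return sp.csr_matrix(adata.layers["counts"])
    return sp.csr_matrix(adata.X)


def ranksum_de(
    adata: ad.AnnData,
    cluster: str,
    mutant: str,
    control: str = "control",
    eps: float = 1e-9,
) -> pd.DataFrame | None:
    """Wilcoxon rank-sum DE of mutant vs. control cells within one cluster.

    Returns a table with columns gene, lfc, p, p_adj, method ("ranksum");
    ``lfc = log2((mean_mut + eps)/(mean_ctl + eps))`` on the expression
    scale. p-values are BH-adjusted across genes. Exact p-values are used
    automatically for small tie-free groups. Returns None (with a warning)
    when either arm has fewer than 3 cells.
    """
    in_cluster = (adata.obs["cluster"].astype(str) == str(cluster)).to_numpy()
    mut_mask = in_cluster & (adata.obs["genotype"] == mutant).to_numpy()
    ctl_mask = in_cluster & (adata.obs["genotype"] == control).to_numpy()
    if mut_mask.sum() < 3 or ctl_mask.sum() < 3:
        warnings.warn(
            f"cluster {cluster}: <3 cells in an arm ({mutant}: {mut_mask.sum()}, "
            f"{control}: {ctl_mask.sum()}); contrast skipped",
            ClusterSkippedWarning,
        )
        return None
    X = _expression(adata)
    A = np.asarray(X[mut_mask].todense())
    B = np.asarray(X[ctl_mask].todense())
    return _ranksum_table(A, B, adata.var_names.to_numpy(), eps=eps)


def _ranksum_table(A: np.ndarray, B: np.ndarray, genes: np.ndarray, eps: float = 1e-9) -> pd.DataFrame:
    small = max(A.shape[0], B.shape[0]) <= 8
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", method="auto" if small else "asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    # Degenerate genes (identical values in both arms) yield nan under the
    # tie-corrected normal approximation; there is no evidence either way.
    constant = np.all(np.concatenate([A, B], axis=0) == A[0:1, :], axis=0)
    p = np.where(np.isnan(p) | constant, 1.0, p)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2((mean_a + eps) / (mean_b + eps))
    lfc = np.where(constant, 0.0, lfc)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": genes, "lfc": lfc, "p": p, "p_adj": p_adj, "method": "ranksum"}
    )


def make_pseudobulks(
    adata: ad.AnnData, cluster: str, min_cells: int = MIN_PSEUDOBULK_CELLS
) -> list[Pseudobulk]:
    """Sum counts per (run, genotype) within a cluster; drop small pseudobulks."""
    in_cluster = (adata.obs["cluster"].astype(str) == str(cluster)).to_numpy()
    sub = adata[in_cluster]
    X = _counts(sub)
    out: list[Pseudobulk] = []
    groups = sub.obs.groupby(["run", "genotype"], observed=True).indices
    for (run, genotype), idx in sorted(groups.items()):
        if len(idx) < min_cells:
            continue
        counts = np.asarray(X[idx].sum(axis=0)).ravel()
        out.append(
            Pseudobulk(
                run_id=str(run),
                genotype=str(genotype),
                cluster=str(cluster),
                counts=counts,
                n_cells=int(len(idx)),
                genes=sub.var_names.to_numpy(),
            )
        )
    return out


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Per-gene MLE of m in mu_i = s_i * m for NB2 with dispersion alpha.

    ``y`` is (n_obs, n_genes); ``s`` is (n_obs,); ``alpha`` is (n_genes,).
    Solves sum_i (y_i - s_i m) / (1 + alpha s_i m) = 0 by damped Newton,
    starting at the Poisson solution m = sum(y)/sum(s).
    """
    m = y.sum(axis=0) / s.sum()
    m = np.maximum(m, 1e-12)
    s_col = s[:, None]
    for _ in range(n_iter):
        denom = 1.0 + alpha[None, :] * s_col * m[None, :]
        f = ((y - s_col * m[None, :]) / denom).sum(axis=0)
        # df/dm = -sum s_i (1 + alpha y_i) / denom^2
        fp = -((s_col * (1.0 + alpha[None, :] * y)) / denom**2).sum(axis=0)
        step = np.where(fp != 0, f / fp, 0.0)
        m_new = np.maximum(m - step, m * 1e-3)
        if np.allclose(m_new, m, rtol=1e-12, atol=1e-15):
            m = m_new
            break
        m = m_new
    return m


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over observations, per gene."""
    r = 1.0 / np.maximum(alpha, 1e-12)[None, :]
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=0)


def _profile_loglik(alpha, y_a, s_a, y_b, s_b):
    m_a = _nb_group_mean(y_a, s_a, alpha)
    m_b = _nb_group_mean(y_b, s_b, alpha)
    ll = _nb_loglik(y_a, s_a[:, None] * m_a[None, :], alpha)
    ll += _nb_loglik(y_b, s_b[:, None] * m_b[None, :], alpha)
    return ll, m_a, m_b


def _fit_dispersion(y_a, s_a, y_b, s_b, lo: float = 1e-8, hi: float = 100.0, n_iter: int = 40):
    """Per-gene profile-ML dispersion by golden-section search on log(alpha)."""
    n_genes = y_a.shape[1]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_genes, np.log(lo))
    b = np.full(n_genes, np.log(hi))
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = _profile_loglik(np.exp(c), y_a, s_a, y_b, s_b)[0]
    fd = _profile_loglik(np.exp(d), y_a, s_a, y_b, s_b)[0]
    for _ in range(n_iter):
        take_left = fc > fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = _profile_loglik(np.exp(c), y_a, s_a, y_b, s_b)[0]
        fd = _profile_loglik(np.exp(d), y_a, s_a, y_b, s_b)[0]
    alpha = np.exp((a + b) / 2.0)
    # Compare against the boundary (Poisson-like) fit; keep the better one.
    ll_mid = _profile_loglik(alpha, y_a, s_a, y_b, s_b)[0]
    alpha_lo = np.full(n_genes, lo)
    ll_lo = _profile_loglik(alpha_lo, y_a, s_a, y_b, s_b)[0]
    alpha = np.where(ll_lo >= ll_mid, alpha_lo, alpha)
    return alpha


def pseudobulk_de(
    pseudobulks: list[Pseudobulk],
    mutant: str,
    control: str = "control",
) -> pd.DataFrame | None:
    """Per-gene NB GLM Wald test of mutant vs. control pseudobulks.

    The model is ``y_ij ~ NB2(mu_ij, alpha_j)`` with ``log mu_ij = log s_i +
    b0_j + b1_j * [i is mutant]`` where ``s_i`` is the pseudobulk library
    size. Dispersion is estimated per gene by profile maximum likelihood
    (floored at 1e-8, no shrinkage). The Wald statistic for ``b1`` is
    referred to a t distribution with ``n_pseudobulks - 2`` degrees of
    freedom, which keeps the test close to nominal at the handful of
    pseudobulks a run-based design yields. Returns None with a warning when
    either arm has fewer than 2 pseudobulks.
    """
    pbs_mut = [pb for pb in pseudobulks if pb.genotype == mutant]
    pbs_ctl = [pb for pb in pseudobulks if pb.genotype == control]
    if len(pbs_mut) < 2 or len(pbs_ctl) < 2:
        warnings.warn(
            f"<2 pseudobulks per arm ({mutant}: {len(pbs_mut)}, {control}: {len(pbs_ctl)}); "
            "contrast skipped",
            ClusterSkippedWarning,
        )
        return None
    y_a = np.stack([pb.counts for pb in pbs_mut]).astype(float)
    y_b = np.stack([pb.counts for pb in pbs_ctl]).astype(float)
    s_a = y_a.sum(axis=1)
    s_b = y_b.sum(axis=1)
    n_genes = y_a.shape[1]

    alpha = _fit_dispersion(y_a, s_a, y_b, s_b)
    _, m_a, m_b = _profile_loglik(alpha, y_a, s_a, y_b, s_b)

    # Floor group rates at half a count per arm library so a zero arm yields a
    # large but finite coefficient with a commensurately large variance.
    floor_a = 0.5 / s_a.sum()
    floor_b = 0.5 / s_b.sum()
    m_a = np.maximum(m_a, floor_a)
    m_b = np.maximum(m_b, floor_b)
    b1 = np.log(m_a) - np.log(m_b)

    mu_a = s_a[:, None] * m_a[None, :]
    mu_b = s_b[:, None] * m_b[None, :]
    info_a = (mu_a / (1.0 + alpha[None, :] * mu_a)).sum(axis=0)
    info_b = (mu_b / (1.0 + alpha[None, :] * mu_b)).sum(axis=0)
    var_b1 = 1.0 / np.maximum(info_a, 1e-300) + 1.0 / np.maximum(info_b, 1e-300)
    df = len(pbs_mut) + len(pbs_ctl) - 2
    tstat = b1 / np.sqrt(var_b1)
    p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df)

    zero_both = (y_a.sum(axis=0) == 0) & (y_b.sum(axis=0) == 0)
    b1 = np.where(zero_both, 0.0, b1)
    p = np.where(zero_both, 1.0, p)

    genes = pbs_mut[0].genes
    if genes is None:
        genes = np.array([f"g{i}" for i in range(n_genes)])
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "lfc": b1 / np.log(2.0),  # natural-log coefficient -> log2 units
            "p": p,
            "p_adj": p_adj,
            "method": "pseudobulk_nb",
        }
    )


def signed_significance(table: pd.DataFrame) -> pd.Series:
    """Per-gene signed score ``lfc x (-log10 p)``.

    Significant upregulated genes score large positive, downregulated large
    negative; p is floored at 1e-300.
    """
    p = np.maximum(table["p"].to_numpy(dtype=float), P_FLOOR)
    score = table["lfc"].to_numpy(dtype=float) * (-np.log10(p))
    return pd.Series(score, index=table["gene"].to_numpy(), name="signed_score")


def method_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Spearman correlation of signed significance on the shared gene set."""
    sa = signed_significance(table_a)
    sb = signed_significance(table_b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    rho, _ = scipy.stats.spearmanr(sa.loc[shared], sb.loc[shared])
    return float(rho)


def downsample_cluster(
    adata: ad.AnnData, cluster: str, n: int, seed: int = 0
) -> ad.AnnData:
    """Downsample the given cluster to ``n`` cells per genotype arm.

    Cells outside the cluster are untouched; within the cluster, a seeded
    uniform subset of ``n`` cells is drawn per genotype. Raises when any arm
    has fewer than ``n`` cells.
    """
    rng = np.random.default_rng(seed)
    in_cluster = (adata.obs["cluster"].astype(str) == str(cluster)).to_numpy()
    keep = ~in_cluster
    for g in sorted(adata.obs.loc[in_cluster, "genotype"].unique()):
        arm = np.flatnonzero(in_cluster & (adata.obs["genotype"] == g).to_numpy())
        if len(arm) < n:
            raise ValueError(f"arm {g} in cluster {cluster} has {len(arm)} < {n} cells")
        chosen = rng.choice(arm, size=n, replace=False)
        keep[chosen] = True
    return adata[keep].copy()


def count_deg(table: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of genes with adjusted p below ``alpha`` (the nDEG statistic)."""
    return int((table["p_adj"] < alpha).sum())
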