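"""Negative-binomial model of DEG counts vs. cluster size.

The number of differentially expressed genes a cluster yields is strongly
driven by how many cells it contains — larger clusters give the tests more
power. To find cell types that are *more affected than their size predicts*,
the per-cluster DEG count ``y_i`` is modeled as over-dispersed count data::

    E[y_i] = mu_i,  Var[y_i] = mu_i + alpha * mu_i^2
    log(mu_i) = intercept + b1 * log(min(x1_i, x2_i))

where ``x1_i`` and ``x2_i`` are the cluster's cell counts in the mutant and
control arms (the smaller arm limits power, hence the min). Residuals
``r_i = y_i - mu_hat_i`` flag clusters with more DEG than expected; ranking
mean residual ranks across genotypes yields the consensus list of commonly
affected cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ClusterStats:
    """Inputs of the vulnerability model for one cluster x genotype contrast."""

    cluster: str
    y: int
    x1: int
    x2: int

    def __post_init__(self):
        if self.y < 0:
            raise ValueError("y must be >= 0")
        if self.x1 < 1 or self.x2 < 1:
            raise ValueError("x1 and x2 must be >= 1")


@dataclass
class NBFit:
    intercept: float
    b1: float
    alpha: float
    loglik: float
    converged: bool = True


def _design(stats: list[ClusterStats]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.y for s in stats], dtype=float)
    x = np.log([min(s.x1, s.x2) for s in stats])
    X = np.column_stack([np.ones_like(x), x])
    return y, X


def fit_nb_model(stats: list[ClusterStats]) -> NBFit:
    """Maximum-likelihood NB2 fit of nDEG on log(min(x1, x2)).

    Degrees of freedom: intercept, slope and the dispersion alpha, all
    estimated jointly by ML. Raises on fewer than 5 clusters or an all-zero
    response (the model is degenerate there).
    """
    if len(stats) < 5:
        raise ValueError("need at least 5 clusters to fit the model")
    y, X = _design(stats)
    if np.all(y == 0):
        raise ValueError("all-zero DEG counts: degenerate fit rejected")
    import warnings

    constant_covariate = np.ptp(X[:, 1]) == 0
    design = X[:, :1] if constant_covariate else X
    model = sm.NegativeBinomial(y, design, loglike_method="nb2")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # alpha pinned at ~0 (equidispersed data) makes the Hessian singular;
        # the point estimates are still valid and that is all we use.
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=200)
    if constant_covariate:
        # all clusters share min(x1, x2): the slope is unidentifiable, so fit
        # the intercept-only (saturated-in-the-mean) model and report b1 = 0
        intercept, b1 = res.params[0], 0.0
        alpha = max(float(res.params[1]), 0.0)
    else:
        intercept, b1 = res.params[0], res.params[1]
        alpha = max(float(res.params[2]), 0.0)
    fit = NBFit(
        intercept=float(intercept),
        b1=float(b1),
        alpha=alpha,
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
    )
    if not np.isfinite(fit.loglik):
        raise ValueError(f"non-convergent NB fit: params={res.params}, loglik={res.llf}")
    return fit


def poisson_loglik(stats: list[ClusterStats]) -> float:
    """Log-likelihood of the Poisson submodel (alpha -> 0) on the same data."""
    y, X = _design(stats)
    res = sm.Poisson(y, X).fit(disp=False)
    return float(res.llf)


def cluster_residuals(fit: NBFit, stats: list[ClusterStats]) -> pd.DataFrame:
    """Observed minus predicted DEG counts per cluster.

    Positive residuals mark clusters with more differential genes than their
    size predicts. Pearson residuals ``r / sqrt(mu + alpha mu^2)`` are
    reported alongside the raw residuals.
    """
    y, X = _design(stats)
    mu_hat = np.exp(X @ np.array([fit.intercept, fit.b1]))
    r = y - mu_hat
    pearson = r / np.sqrt(mu_hat + fit.alpha * mu_hat**2)
    return pd.DataFrame(
        {
            "cluster": [s.cluster for s in stats],
            "y": y.astype(int),
            "mu_hat": mu_hat,
            "r": r,
            "pearson": pearson,
        }
    )


def rank_vulnerable(
    residuals_per_genotype: dict[str, pd.DataFrame],
    top_k: int | None = None,
    use_pearson: bool = False,
) -> pd.DataFrame:
    """Consensus vulnerability ranking across genotypes by mean residual rank.

    Within each genotype, clusters are ranked by residual descending (rank 1 =
    most DEG above expectation; average ranks on ties). Clusters missing from
    a genotype receive that genotype's worst rank. The returned table is
    sorted by mean rank; when ``top_k`` is given, a boolean ``top`` column
    marks the consensus "commonly affected" set.
    """
    if not residuals_per_genotype:
        raise ValueError("no residual tables given")
    col = "pearson" if use_pearson else "r"
    universe = sorted({c for df in residuals_per_genotype.values() for c in df["cluster"].astype(str)})
    ranks = pd.DataFrame(index=universe, dtype=float)
    for genotype, df in residuals_per_genotype.items():
        s = pd.Series(df[col].to_numpy(), index=df["cluster"].astype(str).to_numpy())
        rk = s.rank(ascending=False, method="average")
        rk = rk.reindex(universe)
        worst = len(universe)
        ranks[genotype] = rk.fillna(worst)
    out = pd.DataFrame(
        {
            "cluster": universe,
            "mean_rank": ranks.mean(axis=1).to_numpy(),
            "n_genotypes": ranks.notna().sum(axis=1).to_numpy(),
        }
    ).sort_values(["mean_rank", "cluster"], kind="mergesort").reset_index(drop=True)
    if top_k is not None:
        out["top"] = np.arange(len(out)) < top_k
    return out
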