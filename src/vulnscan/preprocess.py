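"""QC filtering and normalization with fly and human presets.

Cells are filtered on detected genes, total counts and mitochondrial
percentage (computed on raw counts). Normalization follows the standard
scale-and-regress recipe: per-cell scaling to a fixed total, log1p, per-gene
OLS regression against nuisance covariates (total counts, mito percentage),
z-scoring of the residuals and clipping at a maximum value.

Presets::

    fly:   min_genes=200, max_genes=7000, min_counts=500,  max_counts=30000, mito < 15%
    human: min_genes=500, max_genes=7000, min_counts=1000, max_counts=30000, mito < 5%

Gene/count bounds are inclusive; the mitochondrial bound is strict ("below").
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import anndata as ad
import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int
    max_genes: int
    min_counts: int
    max_counts: int
    max_mito_pct: float

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if self.min_counts > self.max_counts:
            raise ValueError("min_counts > max_counts")
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must lie in [0, 100]")


FLY_QC = QCThresholds(min_genes=200, max_genes=7000, min_counts=500, max_counts=30000, max_mito_pct=15)
HUMAN_QC = QCThresholds(min_genes=500, max_genes=7000, min_counts=1000, max_counts=30000, max_mito_pct=5)
PRESETS = {"fly": FLY_QC, "human": HUMAN_QC}


@dataclass
class QCReport:
    """Cell-filtering summary; removals are attributed to the first failing rule."""

    n_in: int
    n_out: int
    removed: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _cell_stats(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = sp.csr_matrix(adata.X)
    n_genes = X.getnnz(axis=1)
    total = np.asarray(X.sum(axis=1)).ravel()
    if "mito" in adata.var:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(total > 0, 100.0 * mito_counts / total, 0.0)
    else:
        mito_pct = None
    return n_genes, total, mito_pct


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds) -> tuple[ad.AnnData, QCReport]:
    """Retain cells passing all thresholds; the gene set is unchanged.

    Bounds on genes and counts are inclusive; the mitochondrial percentage
    must be strictly below ``max_mito_pct``, computed on raw counts.
    """
    n_genes, total, mito_pct = _cell_stats(adata)
    if mito_pct is None:
        if thresholds.max_mito_pct < 100:
            raise ValueError("gene metadata lacks 'mito' flags but a mito threshold is set")
        mito_pct = np.zeros(adata.n_obs)

    rules = [
        ("min_genes", n_genes < thresholds.min_genes),
        ("max_genes", n_genes > thresholds.max_genes),
        ("min_counts", total < thresholds.min_counts),
        ("max_counts", total > thresholds.max_counts),
        ("max_mito_pct", mito_pct >= thresholds.max_mito_pct),
    ]
    keep = np.ones(adata.n_obs, dtype=bool)
    removed = {}
    for name, fails in rules:
        newly = fails & keep
        removed[name] = int(newly.sum())
        keep &= ~fails
    report = QCReport(n_in=int(adata.n_obs), n_out=int(keep.sum()), removed=removed)
    return adata[keep].copy(), report


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4, layer: str = "lognorm") -> ad.AnnData:
    """Scale each cell to ``scale_factor`` total counts, then log1p.

    Raw counts are preserved in ``.layers['counts']``; the log-normalized
    matrix becomes ``.X`` (and is mirrored in ``.layers[layer]``).
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError("cells with zero total counts; filter first")
    scaled = sp.diags(scale_factor / total) @ X
    scaled.data = np.log1p(scaled.data)
    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(adata.X)
    out.X = scaled
    out.layers[layer] = scaled.copy()
    return out


def normalize(
    adata: ad.AnnData,
    scale_factor: float = 1e4,
    clip_max: float = 10.0,
    covariates=("total_counts", "mito_pct"),
) -> ad.AnnData:
    """Full normalization: log-normalize, regress out covariates, scale, clip.

    Per gene, the log-normalized values are replaced by the residuals of an
    OLS fit against the requested per-cell covariates (computed on raw
    counts), then z-scored and clipped at ``+clip_max``. The result is stored
    densely in ``.layers['scaled']``; ``.X`` holds the log-normalized matrix.
    """
    n_genes_det, total, mito_pct = _cell_stats(adata)
    out = log_normalize(adata, scale_factor=scale_factor)

    cols = [np.ones(out.n_obs)]
    for cov in covariates:
        if cov == "total_counts":
            cols.append(total.astype(float))
        elif cov == "mito_pct":
            if mito_pct is None:
                raise ValueError("mito_pct covariate requested but no mito flags present")
            cols.append(mito_pct.astype(float))
        elif cov == "n_genes":
            cols.append(n_genes_det.astype(float))
        else:
            raise ValueError(f"unknown covariate: {cov!r}")
    C = np.column_stack(cols)

    Y = np.asarray(out.X.todense(), dtype=float)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta

    sd = resid.std(axis=0, ddof=0)
    # genes whose residuals are numerically zero carry no signal; z-scoring
    # them would only amplify floating-point noise
    spread = np.abs(Y).max(axis=0) + 1.0
    degenerate = sd <= 1e-12 * spread
    sd[degenerate] = np.inf
    scaled = resid / sd
    np.minimum(scaled, clip_max, out=scaled)
    out.layers["scaled"] = scaled
    return out
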