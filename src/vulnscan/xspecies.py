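"""Cross-species gene mapping, set overlap, and per-cell gene-set enrichment.

Orthologue maps carry integer confidence scores (DIOPT-style); pairs below a
minimum score (default 5) are ignored and many-to-many mappings resolve to
the best-scoring partner. Overlap between a mapped deregulated set and a
second species' deregulated set is quantified as a fraction plus an
upper-tail hypergeometric p-value over an explicit gene universe. Per-cell
gene-set activity is scored AUCell-style: the area under the gene-set
recovery curve within the top fraction of each cell's expression ranking,
normalized to [0, 1] by the maximum achievable area; group differences are
assessed with a two-tailed two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class OverlapResult:
    N: int  # universe size
    K: int  # flagged-in-universe (set B)
    n: int  # draw size (set A)
    k: int  # observed overlap
    fraction: float | None
    p_upper: float | None


def map_orthologs(
    genes, ortholog_map: pd.DataFrame, min_score: int = 5
) -> tuple[list[str], int]:
    """Translate genes through an orthologue map at a minimum confidence score.

    ``ortholog_map`` has columns fly_gene, human_gene, score. Genes with at
    least one pair at ``score >= min_score`` are translated; a gene with
    several admissible partners maps to the best score, ties broken
    lexicographically on the partner id. Returns the translated list (in
    input order, duplicates possible when two inputs share a partner) and the
    number of unmapped genes dropped.
    """
    ok = ortholog_map[ortholog_map["score"] >= min_score]
    best: dict[str, str] = {}
    for fly, grp in ok.groupby("fly_gene"):
        grp = grp.sort_values(["score", "human_gene"], ascending=[False, True], kind="mergesort")
        best[fly] = str(grp["human_gene"].iloc[0])
    mapped, unmapped = [], 0
    for g in genes:
        if g in best:
            mapped.append(best[g])
        else:
            unmapped += 1
    return mapped, unmapped


def overlap_stats(set_a, set_b, universe) -> OverlapResult:
    """Overlap of set A with set B inside a universe, with hypergeometric p.

    ``fraction = |A ∩ B| / |A|``; ``p_upper`` is the probability of drawing
    at least the observed overlap when |A| genes are drawn uniformly without
    replacement from the universe containing |B| flagged genes. An empty set
    A yields fraction and p as None.
    """
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("set A and set B must be subsets of the universe")
    N, K, n = len(universe), len(b), len(a)
    k = len(a & b)
    if n == 0:
        return OverlapResult(N=N, K=K, n=0, k=0, fraction=None, p_upper=None)
    p_upper = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(N=N, K=K, n=n, k=k, fraction=k / n, p_upper=p_upper)


def aucell_scores(
    expression: np.ndarray,
    gene_names,
    gene_set,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell AUC of the gene-set recovery curve within the top ranks.

    ``expression`` is cells x genes. Per cell, genes are ranked by expression
    descending with seeded random tie-breaking; the recovery curve counts
    gene-set members among the top ``ceil(top_fraction * n_genes)`` ranks and
    its area is normalized by the maximum achievable area (all members at the
    very top), giving a score in [0, 1].
    """
    expression = np.asarray(expression, dtype=float)
    gene_names = np.asarray(gene_names)
    in_set = np.isin(gene_names, list(gene_set))
    if not in_set.any():
        raise ValueError("gene set does not intersect the expression matrix genes")
    n_cells, n_genes = expression.shape
    window = int(np.ceil(top_fraction * n_genes))
    m = int(in_set.sum())
    max_auc = sum(min(i, m) for i in range(1, window + 1))
    rng = np.random.default_rng(seed)
    scores = np.empty(n_cells)
    for i in range(n_cells):
        order = np.lexsort((rng.random(n_genes), -expression[i]))
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(1, n_genes + 1)
        set_ranks = ranks[in_set]
        hits = set_ranks[set_ranks <= window]
        scores[i] = (window - hits + 1).sum() / max_auc
    return scores


def enrichment_test(scores_a, scores_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default) on per-cell AUC scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
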