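"""Cross-genotype convergence by signed rank aggregation.

For each genotype, genes are ranked by their signed significance (rank 1 =
most upregulated, rank n = most downregulated; average ranks on ties). Ranks
are summed across genotypes and genes are sorted by the summed rank: the top
``tail_fraction`` are the *common upregulated* genes (consistently near the
top in every genotype) and the bottom ``tail_fraction`` the *common
downregulated* genes. A gene deregulated in only one genotype lands mid-list;
only consistent deregulation reaches a tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detest import signed_significance


@dataclass
class ConvergenceResult:
    ranks: pd.DataFrame  # genes x genotypes, signed ranks
    summed: pd.Series  # summed rank per gene, sorted ascending
    tail_fraction: float
    common_up: list = field(default_factory=list)
    common_down: list = field(default_factory=list)


def rank_genes_signed(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-genotype signed-significance ranks on the shared gene universe.

    ``tables`` maps genotype -> DE table. Genes are the intersection across
    genotypes; rank 1 is the most upregulated gene (highest signed score),
    ties get average ranks.
    """
    if not tables:
        raise ValueError("no DE tables given")
    scores = {g: signed_significance(t) for g, t in tables.items()}
    universe: pd.Index | None = None
    for s in scores.values():
        universe = s.index if universe is None else universe.intersection(s.index)
    if universe is None or len(universe) == 0:
        raise ValueError("empty gene intersection across genotypes")
    universe = universe.sort_values()
    ranks = pd.DataFrame(
        {g: s.loc[universe].rank(ascending=False, method="average") for g, s in scores.items()}
    )
    ranks.index.name = "gene"
    return ranks


def aggregate_ranks(ranks: pd.DataFrame, tail_fraction: float = 0.05) -> ConvergenceResult:
    """Sum ranks across genotypes and retain the extreme tails.

    Genes are sorted by summed rank ascending (ties broken by gene id for
    determinism); the first ``ceil(f * n)`` genes are ``common_up``, the last
    ``ceil(f * n)`` are ``common_down``. ``f > 0.5`` would make the tails
    overlap and is rejected.
    """
    if ranks.shape[1] < 2:
        raise ValueError("need at least 2 genotypes to aggregate")
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5]")
    summed = ranks.sum(axis=1)
    order = summed.reset_index()
    order.columns = ["gene", "summed"]
    order = order.sort_values(["summed", "gene"], kind="mergesort")
    n = len(order)
    k = math.ceil(tail_fraction * n)
    if 2 * k > n:
        raise ValueError("tail sets would overlap at this tail_fraction")
    common_up = order["gene"].iloc[:k].tolist()
    common_down = order["gene"].iloc[-k:].tolist()
    summed_sorted = pd.Series(
        order["summed"].to_numpy(), index=order["gene"].to_numpy(), name="summed_rank"
    )
    return ConvergenceResult(
        ranks=ranks,
        summed=summed_sorted,
        tail_fraction=tail_fraction,
        common_up=common_up,
        common_down=common_down,
    )


def converge(tables: dict[str, pd.DataFrame], tail_fraction: float = 0.05) -> ConvergenceResult:
    """Rank and aggregate in one call."""
    return aggregate_ranks(rank_genes_signed(tables), tail_fraction=tail_fraction)
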