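"""Comprehensive (RefFinder-style) ranking across stability methods.

Each contributing method (geNorm, NormFinder, BestKeeper, comparative
delta-Ct) produces a per-gene rank; the comprehensive score is the geometric
mean of a gene's ranks over the methods, and the final ranking sorts that
geometric mean ascending.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import ValidationError

__all__ = ["AggregateRanking", "ranks_from_scores", "reffinder_aggregate"]


@dataclass(frozen=True)
class AggregateRanking:
    """Comprehensive ranking table.

    ``table`` has one column of ranks per method plus ``geomean`` and
    ``final_rank``; ``winner`` is the top gene (ties broken by gene id).
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    @property
    def winner(self) -> str:
        return str(self.table.index[0])

    @property
    def final_order(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def ranks_from_scores(scores: pd.Series, ascending: bool = True) -> pd.Series:
    """Average (fractional) ranks from stability scores.

    With *ascending* (the convention for all four methods here: smaller
    score = more stable), the smallest score gets rank 1.  Tied scores
    receive the mean of the positions they occupy.
    """
    values = pd.Series(scores).astype(float)
    if not np.all(np.isfinite(values.to_numpy())):
        raise ValidationError("scores must be finite")
    r = rankdata(values.to_numpy() if ascending else -values.to_numpy(),
                 method="average")
    return pd.Series(r, index=values.index, name="rank")


def reffinder_aggregate(rankings: Mapping[str, pd.Series]) -> AggregateRanking:
    """Geometric-mean aggregation of per-method rankings.

    *rankings* maps method name -> per-gene ranks over an identical gene
    set.  A single method passes through unchanged (the geometric mean of
    one rank is that rank).
    """
    if not rankings:
        raise ValidationError("no rankings supplied")
    methods = tuple(rankings)
    frames = {m: pd.Series(r).astype(float) for m, r in rankings.items()}
    gene_sets = [frozenset(s.index) for s in frames.values()]
    if len(set(gene_sets)) != 1:
        raise ValidationError("all methods must rank the identical gene set")
    genes = list(frames[methods[0]].index)
    table = pd.DataFrame({m: frames[m].reindex(genes) for m in methods})
    table["geomean"] = np.exp(np.log(table[list(methods)]).mean(axis=1))
    order = sorted(genes, key=lambda g: (table.loc[g, "geomean"], g))
    table = table.loc[order]
    table["final_rank"] = np.arange(1, len(order) + 1)
    return AggregateRanking(table=table, methods=methods)
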