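"""Descriptive stability screening on raw Ct values.

Two classic, model-free approaches:

* BestKeeper-style screening: a gene's stability is judged from the
  dispersion of its raw Ct across samples (SD and CV).  SD below 1 cycle is
  the conventional "stable" threshold.  An optional BestKeeper index -- the
  per-sample geometric mean Ct across the stable panel -- gives each gene a
  Pearson correlation with the panel consensus.
* The comparative delta-Ct method: for every gene pair the per-sample Ct
  difference is formed and its SD taken; a gene's score is the mean pair SD
  against all other candidates.  On a perfect-efficiency quantity scale this
  is algebraically identical to the geNorm M value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtTable, ValidationError

__all__ = [
    "BestkeeperResult",
    "DeltaCtResult",
    "bestkeeper_stats",
    "bestkeeper_index",
    "delta_ct_stability",
]

SD_MODES = ("sample_sd", "mean_abs_dev")


@dataclass(frozen=True)
class BestkeeperResult:
    """Per-gene descriptive statistics of raw Ct.

    ``table`` columns: mean_ct, min_ct, max_ct, sd, cv_percent, stable.
    ``unsuitable`` is set when no gene passes the SD threshold, in which case
    the method cannot discriminate reference genes for this design.
    """

    table: pd.DataFrame
    sd_mode: str
    threshold: float
    unsuitable: bool

    @property
    def advisory(self) -> Optional[str]:
        if self.unsuitable:
            return (
                f"no gene has {self.sd_mode} < {self.threshold}; BestKeeper "
                "screening is unsuitable for this sample design"
            )
        return None


@dataclass(frozen=True)
class DeltaCtResult:
    """Comparative delta-Ct scores (mean pairwise delta-Ct SD, cycles)."""

    scores: pd.Series
    ranks: pd.Series


def _dispersion(ct: np.ndarray, sd_mode: str) -> np.ndarray:
    if sd_mode == "sample_sd":
        return ct.std(axis=1, ddof=1)
    if sd_mode == "mean_abs_dev":
        # the original BestKeeper reports mean absolute deviation from the mean
        return np.abs(ct - ct.mean(axis=1, keepdims=True)).mean(axis=1)
    raise ValidationError(f"sd_mode must be one of {SD_MODES}, got {sd_mode!r}")


def bestkeeper_stats(
    table: CtTable, sd_mode: str = "sample_sd", threshold: float = 1.0
) -> BestkeeperResult:
    """Per-gene mean/min/max/SD/CV of raw Ct plus a stability flag.

    CV is reported as a percentage of the mean Ct.  A gene is flagged stable
    when its dispersion is below *threshold* cycles; when no gene qualifies,
    the result carries an advisory that the method is unsuitable.
    """
    if table.n_samples < 2:
        raise ValidationError("descriptive screening needs >= 2 samples")
    sd = _dispersion(table.ct, sd_mode)
    mean = table.ct.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_ct": mean,
            "min_ct": table.ct.min(axis=1),
            "max_ct": table.ct.max(axis=1),
            "sd": sd,
            "cv_percent": 100.0 * sd / mean,
            "stable": sd < threshold,
        },
        index=list(table.gene_ids),
    )
    return BestkeeperResult(
        table=out,
        sd_mode=sd_mode,
        threshold=threshold,
        unsuitable=not bool(out["stable"].any()),
    )


def bestkeeper_index(
    table: CtTable, genes: Optional[Sequence[str]] = None
) -> tuple[pd.Series, pd.DataFrame]:
    """BestKeeper index and per-gene correlation against it.

    The index is the per-sample geometric mean of the listed genes' Ct.
    Returns ``(index, correlations)`` where *correlations* has columns
    ``r`` and ``p`` (Pearson, gene Ct vs index); a zero-variance gene or
    index leaves r and p as NaN.
    """
    genes = list(genes) if genes is not None else list(table.gene_ids)
    if len(genes) < 2:
        raise ValidationError("the index needs >= 2 genes")
    if table.n_samples < 3:
        raise ValidationError("correlations need >= 3 samples")
    sub = table.subset_genes(genes)
    index = pd.Series(
        np.exp(np.log(sub.ct).mean(axis=0)),
        index=list(table.sample_ids),
        name="bestkeeper_index",
    )
    rows = {}
    idx_const = np.ptp(index.to_numpy()) == 0
    for i, gene in enumerate(genes):
        x = sub.ct[i]
        if idx_const or np.ptp(x) == 0:
            rows[gene] = (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(x, index.to_numpy())
            rows[gene] = (float(r), float(p))
    corr = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p"])
    return index, corr


def delta_ct_stability(table: CtTable) -> DeltaCtResult:
    """Comparative delta-Ct stability: mean SD of pairwise Ct differences.

    For genes i, i' the per-sample difference Ct_i - Ct_i' has SD s_ii'
    (n-1 denominator); gene i's score is the mean of s_ii' over i' != i.
    Ranking is ascending (lower = more stable), ties broken by gene id.
    """
    if table.n_genes < 2 or table.n_samples < 2:
        raise ValidationError("need >= 2 genes and >= 2 samples")
    ct = table.ct
    k = table.n_genes
    pair_sd = np.zeros((k, k))
    for i in range(k):
        pair_sd[i] = (ct[i] - ct).std(axis=1, ddof=1)
    scores = pd.Series(
        pair_sd.sum(axis=1) / (k - 1), index=list(table.gene_ids), name="mean_pair_sd"
    )
    order = sorted(scores.index, key=lambda g: (scores[g], g))
    ranks = pd.Series(
        {g: float(i + 1) for i, g in enumerate(order)}, name="rank"
    ).reindex(scores.index)
    return DeltaCtResult(scores=scores, ranks=ranks)
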