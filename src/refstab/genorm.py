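"""geNorm stability analysis.

geNorm scores each candidate reference gene by its expression stability
measure M: the arithmetic mean of the pairwise variations V_jk between the
gene and every other candidate, where V_jk is the standard deviation over
samples of the log2 expression ratio of the two genes.  Genes whose
expression rises and falls together (the hallmark of good reference genes)
have constant ratios and hence low M.

The algorithm then iteratively removes the least stable gene (highest M) and
recomputes M on the survivors, yielding a ranking whose final two genes are
indistinguishable (their mutual ratio is all the information left) and are
reported as a tied best pair.

The optimal number of reference genes is chosen from the pairwise variation
V_n/n+1 between normalization factors built from the n and n+1 most stable
genes: once V_n/n+1 drops below a cutoff (0.15 by convention), adding the
(n+1)-th gene no longer changes normalization meaningfully.

All log-ratios use base 2 and all standard deviations use the n-1
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import QuantityLike, ValidationError, as_quantity_frame

__all__ = [
    "GenormResult",
    "pairwise_variation_matrix",
    "m_values",
    "stepwise_ranking",
    "normalization_factor",
    "pairwise_v",
    "genorm",
]


@dataclass(frozen=True)
class GenormResult:
    """Full output of a geNorm run."""

    #: M computed on the full candidate set (the values usually plotted).
    m: pd.Series
    #: Genes ordered most to least stable; the first two are a tied pair.
    order: tuple[str, ...]
    #: Removal order during stepwise exclusion (first removed = least stable).
    removal_order: tuple[str, ...]
    #: Rank per gene for aggregation: the top pair shares rank 1.5.
    ranks: pd.Series
    #: (n, V_n/n+1) pairs for n = 2 .. k-1.
    v_curve: tuple[tuple[int, float], ...]
    #: Smallest n with V_n/n+1 < cutoff, or None (continue screening).
    recommended_n: Optional[int]
    cutoff: float


def pairwise_variation_matrix(q: QuantityLike) -> pd.DataFrame:
    """Symmetric matrix of pairwise variations V_jk.

    V_jk is the sample standard deviation (n-1 denominator) over samples of
    log2(q_j / q_k).  The diagonal is zero.
    """
    frame = as_quantity_frame(q)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValidationError("need at least 2 genes and 2 samples")
    y = np.log2(frame.to_numpy())
    k = y.shape[0]
    v = np.zeros((k, k))
    for j in range(k):
        diff = y[j] - y  # (k, n_samples) of log-ratios against gene j
        v[j] = diff.std(axis=1, ddof=1)
    v = 0.5 * (v + v.T)  # symmetric up to float noise already; make exact
    return pd.DataFrame(v, index=frame.index, columns=frame.index)


def m_values(q: QuantityLike, genes: Optional[Sequence[str]] = None) -> pd.Series:
    """Stability measure M per gene: mean pairwise variation within *genes*.

    When *genes* is None the full candidate set is used.
    """
    frame = as_quantity_frame(q)
    if genes is not None:
        frame = frame.loc[list(genes)]
    if frame.shape[0] < 2:
        raise ValidationError("M is defined only for >= 2 genes")
    v = pairwise_variation_matrix(frame)
    k = frame.shape[0]
    return (v.sum(axis=1)) / (k - 1)


def stepwise_ranking(q: QuantityLike) -> GenormResult:
    """Rank genes by iterative exclusion of the least stable candidate.

    At each round M is recomputed on the surviving subset and the gene with
    the highest M is removed (ties broken by lexicographically smallest gene
    id among the tied worst, so runs are reproducible).  The ranking is the
    reverse removal order; the final two genes cannot be distinguished and
    share the top rank (1.5 each).
    """
    frame = as_quantity_frame(q)
    if frame.shape[0] < 3:
        raise ValidationError("stepwise ranking needs >= 3 genes")
    surviving = list(frame.index)
    removed: list[str] = []
    while len(surviving) > 2:
        m = m_values(frame, surviving)
        worst_m = m.max()
        worst = sorted(g for g in surviving if m[g] == worst_m)[0]
        surviving.remove(worst)
        removed.append(worst)
    top_pair = sorted(surviving)
    order = tuple(top_pair + removed[::-1])
    ranks = pd.Series(index=list(order), dtype=float)
    ranks.iloc[0] = ranks.iloc[1] = 1.5
    ranks.iloc[2:] = np.arange(3, len(order) + 1, dtype=float)
    ranks = ranks.reindex(frame.index)
    full_m = m_values(frame)
    return GenormResult(
        m=full_m,
        order=order,
        removal_order=tuple(removed),
        ranks=ranks,
        v_curve=(),
        recommended_n=None,
        cutoff=np.nan,
    )


def normalization_factor(
    q: QuantityLike, ordered_genes: Sequence[str], n: int
) -> pd.Series:
    """Per-sample normalization factor NF_n.

    NF_n(sample) is the geometric mean over the *n* most stable genes (the
    first *n* entries of *ordered_genes*) of their relative quantities in
    that sample.
    """
    frame = as_quantity_frame(q)
    if not (2 <= n <= len(ordered_genes)):
        raise ValidationError(f"n={n} out of range [2, {len(ordered_genes)}]")
    top = list(ordered_genes[:n])
    sub = np.log2(frame.loc[top].to_numpy())
    return pd.Series(2.0 ** sub.mean(axis=0), index=frame.columns, name=f"NF_{n}")


def pairwise_v(
    q: QuantityLike,
    ordered_genes: Optional[Sequence[str]] = None,
    cutoff: float = 0.15,
) -> tuple[tuple[tuple[int, float], ...], Optional[int]]:
    """Pairwise variation V_n/n+1 curve and the recommended gene count.

    V_n/n+1 is the standard deviation over samples of log2(NF_n / NF_{n+1}).
    The recommended number of reference genes is the smallest n whose
    V_n/n+1 falls below *cutoff*; when no V does, ``None`` is returned and
    screening should continue with more candidates.
    """
    frame = as_quantity_frame(q)
    if frame.shape[0] < 3:
        raise ValidationError("the V curve needs >= 3 genes")
    if ordered_genes is None:
        ordered_genes = stepwise_ranking(frame).order
    y = np.log2(frame.loc[list(ordered_genes)].to_numpy())
    curve: list[tuple[int, float]] = []
    for n in range(2, len(ordered_genes)):
        log_nf_n = y[:n].mean(axis=0)
        log_nf_n1 = y[: n + 1].mean(axis=0)
        v = float(np.std(log_nf_n - log_nf_n1, ddof=1))
        curve.append((n, v))
    recommended = next((n for n, v in curve if v < cutoff), None)
    return tuple(curve), recommended


def genorm(q: QuantityLike, cutoff: float = 0.15) -> GenormResult:
    """Run the complete geNorm analysis: M values, ranking, and V curve."""
    base = stepwise_ranking(q)
    curve, recommended = pairwise_v(q, base.order, cutoff)
    return GenormResult(
        m=base.m,
        order=base.order,
        removal_order=base.removal_order,
        ranks=base.ranks,
        v_curve=curve,
        recommended_n=recommended,
        cutoff=cutoff,
    )
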