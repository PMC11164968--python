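"""Model-based (NormFinder-style) stability analysis.

Candidate reference genes are scored by decomposing their log2 relative
quantities into intra-group variance (how noisy a gene is within an
experimental group) and inter-group bias (how much a gene's level departs
from the panel consensus between groups).  A gene that is quiet within groups
and unbiased across groups is a good normalizer.

Model, on y = log2(Q) for gene i, group g, sample j:

    y_igj = alpha_i + beta_g + d_ig + b_gj + eps_igj,
    eps_igj ~ N(0, sigma2_ig)

where b_gj is a per-sample loading effect shared by all genes (cDNA input
differences) and d_ig is the gene x group interaction -- the inter-group bias
of interest.  Centering each sample's column across genes removes b_gj; the
remaining contamination of each gene's within-group variance by the panel
average is removed by a method-of-moments correction.

Estimators (k = number of genes, n_g = samples in group g):

* d_ig  = cell mean minus gene and group main effects plus the grand mean
  (gene and grand means weight cells by group size).  Within every group the
  d_ig sum to zero over genes.
* with z_igj = y_igj - mean over genes of y_.gj and u_ig = sample variance of
  z over j within the group:

      sigma2_ig = max(0, (u_ig - u_bar_g / (k-1)) * k / (k-2))

  which is consistent because Var(z_ig.) = sigma2_ig (1 - 2/k) + S_g / k**2
  with S_g the summed noise variance of the panel.  The k/(k-2) factor
  requires k >= 3.

The stability value combines both sources:

    SV_i = (1/G) * sum_g sqrt(d_ig**2 + sigma2_ig / n_g)

For a single group there is no inter-group term and SV_i = sqrt(sigma2_i).
Lower SV = more stable; ranking is ascending with ties broken by gene id.

This estimator reproduces the published method's intent (an ANOVA-style
intra- plus inter-group decomposition) but applies no shrinkage to the
inter-group differences; the result header notes this.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_model import QuantityLike, QuantityTable, ValidationError, as_quantity_frame

__all__ = ["NormfinderResult", "decompose_variance", "stability_values", "normfinder"]

_HEADER_NOTE = (
    "method-of-moments intra/inter-group decomposition; "
    "no shrinkage applied to inter-group differences"
)


@dataclass(frozen=True)
class NormfinderResult:
    """Per-gene stability values with the underlying decomposition."""

    #: gene x group inter-group deviation, log2 units; rows sum to ~0 per column.
    d: pd.DataFrame
    #: gene x group intra-group variance, log2^2 units, truncated at 0.
    sigma2: pd.DataFrame
    #: gene x group flags set where truncation to 0 fired.
    truncated: pd.DataFrame
    #: combined stability value per gene, log2 units (lower = stabler).
    sv: pd.Series
    #: rank 1..k ascending by SV, ties broken by gene id.
    ranks: pd.Series
    group_sizes: Mapping[str, int]
    note: str = _HEADER_NOTE


def _resolve_groups(
    q: QuantityLike, groups: Optional[Mapping[str, str]]
) -> tuple[pd.DataFrame, np.ndarray]:
    frame = as_quantity_frame(q)
    if isinstance(q, QuantityTable) and groups is None:
        labels = q.sample_groups()
    elif groups is not None:
        labels = np.array([str(groups[s]) for s in frame.columns])
    else:
        raise ValidationError(
            "group labels required: pass a QuantityTable or a groups mapping"
        )
    return frame, labels


def decompose_variance(
    q: QuantityLike, groups: Optional[Mapping[str, str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Estimate inter-group deviations d_ig and intra-group variances sigma2_ig.

    Returns ``(d, sigma2, truncated)`` as gene x group DataFrames; *truncated*
    marks cells where a negative moment estimate was clipped to zero.
    Requires at least 3 genes and at least 2 samples in every group.
    """
    frame, labels = _resolve_groups(q, groups)
    y = np.log2(frame.to_numpy())
    k = y.shape[0]
    if k < 3:
        raise ValidationError(
            "the variance correction needs >= 3 genes (factor k/(k-2))"
        )
    group_order = list(dict.fromkeys(labels))
    cols = {g: np.flatnonzero(labels == g) for g in group_order}
    sizes = {g: len(ix) for g, ix in cols.items()}
    for g, n_g in sizes.items():
        if n_g < 2:
            raise ValidationError(f"group {g!r} has {n_g} sample(s); need >= 2")
    n_total = y.shape[1]

    # interaction estimate on group-size-weighted means
    cell = np.column_stack([y[:, cols[g]].mean(axis=1) for g in group_order])
    w = np.array([sizes[g] for g in group_order], dtype=float) / n_total
    gene_mean = cell @ w                      # = mean over all samples per gene
    group_mean = cell.mean(axis=0)            # mean over genes of cell means
    grand = float(group_mean @ w)
    d = cell - gene_mean[:, None] - group_mean[None, :] + grand

    # intra-group variance via sample-centered residuals
    z = y - y.mean(axis=0, keepdims=True)
    sigma2 = np.empty_like(d)
    truncated = np.zeros_like(d, dtype=bool)
    for gi, g in enumerate(group_order):
        u = z[:, cols[g]].var(axis=1, ddof=1)
        u_bar = u.mean()
        raw = (u - u_bar / (k - 1)) * k / (k - 2)
        truncated[:, gi] = raw < 0
        sigma2[:, gi] = np.maximum(raw, 0.0)

    idx = frame.index
    return (
        pd.DataFrame(d, index=idx, columns=group_order),
        pd.DataFrame(sigma2, index=idx, columns=group_order),
        pd.DataFrame(truncated, index=idx, columns=group_order),
    )


def stability_values(
    d: pd.DataFrame,
    sigma2: pd.DataFrame,
    group_sizes: Mapping[str, int],
) -> tuple[pd.Series, pd.Series]:
    """Combine the decomposition into per-gene stability values and ranks.

    Multi-group: SV_i = mean over groups of sqrt(d_ig^2 + sigma2_ig / n_g).
    Single group: SV_i = sqrt(sigma2_i) (no inter-group term exists).
    """
    groups = list(d.columns)
    if len(groups) == 1:
        sv = np.sqrt(sigma2.iloc[:, 0])
    else:
        n = np.array([group_sizes[g] for g in groups], dtype=float)
        per_group = np.sqrt(d.to_numpy() ** 2 + sigma2.to_numpy() / n[None, :])
        sv = pd.Series(per_group.mean(axis=1), index=d.index)
    sv = sv.rename("SV")
    order = sorted(sv.index, key=lambda g: (sv[g], g))
    ranks = pd.Series(
        {g: float(i + 1) for i, g in enumerate(order)}, name="rank"
    ).reindex(sv.index)
    return sv, ranks


def normfinder(
    q: QuantityLike,
    groups: Optional[Mapping[str, str]] = None,
    ungrouped: bool = False,
) -> NormfinderResult:
    """Run the full decomposition and scoring.

    With *ungrouped* all samples are pooled into one group, reducing the
    score to the within-set noise sqrt(sigma2) -- useful when the grouping of
    a sample series is not meaningful.
    """
    frame, labels = _resolve_groups(q, groups)
    if ungrouped:
        labels = np.array(["all"] * frame.shape[1])
    gmap = {s: g for s, g in zip(frame.columns, labels)}
    d, sigma2, truncated = decompose_variance(frame, gmap)
    sizes = {g: int((labels == g).sum()) for g in d.columns}
    if len(d.columns) == 1:
        d = d * 0.0  # single group: inter-group deviation undefined, set 0
    sv, ranks = stability_values(d, sigma2, sizes)
    return NormfinderResult(
        d=d, sigma2=sigma2, truncated=truncated, sv=sv, ranks=ranks,
        group_sizes=sizes,
    )
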