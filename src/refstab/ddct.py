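"""2^-ddCt relative quantification and transcriptome concordance.

The classic comparative-Ct method: a target gene's expression in condition c,
relative to a calibrator condition and normalized by one or more reference
genes, is

    dCt(c)  = mean target Ct in c  -  mean reference Ct in c
    ddCt(c) = dCt(c) - dCt(calibrator)
    fold    = 2 ** -ddCt(c)

Several reference genes are combined by the arithmetic mean of their Ct,
which is the geometric mean of their quantities.  An efficiency-corrected
variant (per-gene base 1 + E instead of 2) is available behind a flag.

Concordance scoring ranks candidate reference genes by how closely the qPCR
fold changes they produce match fold changes from an expression matrix
(e.g. RNA-seq): distance = mean |log2 fold_qPCR - log2 fold_expr| over
targets and conditions, smaller = better.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data_model import CtTable, EfficiencyMap, ValidationError

__all__ = ["DdctResult", "ConcordanceReport", "delta_delta_ct", "concordance"]


@dataclass(frozen=True)
class DdctResult:
    """Tidy table of dCt / ddCt / fold per target x condition.

    ``table`` columns: target, condition, dct, dct_sd, ddct, fold.
    ``dct_sd`` is the SD over replicates of the per-sample dCt (NaN with a
    single replicate); the mean per-replicate dCt equals the difference of
    means, so point estimates do not depend on replicate handling.
    """

    table: pd.DataFrame
    references: tuple[str, ...]
    calibrator: str

    def fold(self, target: str, condition: str) -> float:
        sel = self.table[
            (self.table["target"] == target) & (self.table["condition"] == condition)
        ]
        if sel.empty:
            raise KeyError((target, condition))
        return float(sel["fold"].iloc[0])

    def folds(self) -> pd.DataFrame:
        """Targets x conditions pivot of fold changes."""
        return self.table.pivot(index="target", columns="condition", values="fold")


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-reference mean |log2 qPCR fold - log2 expression fold|."""

    table: pd.DataFrame  # index: reference gene; columns: distance, rank

    @property
    def best(self) -> str:
        return str(self.table.index[0])


def delta_delta_ct(
    ct: CtTable,
    targets: Sequence[str],
    references: Sequence[str],
    calibrator: str,
    efficiencies: Optional[EfficiencyMap] = None,
) -> DdctResult:
    """Relative expression of *targets* normalized by *references*.

    Conditions are the group labels of *ct*; *calibrator* names the baseline
    condition (its own fold change is exactly 1).  Target and reference sets
    must be disjoint.  With *efficiencies*, the efficiency-corrected variant
    is used: each gene amplifies with its own base 1 + E rather than 2.
    """
    targets = list(targets)
    references = list(references)
    if not targets or not references:
        raise ValidationError("need at least one target and one reference")
    overlap = set(targets) & set(references)
    if overlap:
        raise ValidationError(f"targets and references overlap: {sorted(overlap)}")
    conditions = ct.group_labels()
    if calibrator not in conditions:
        raise ValidationError(
            f"calibrator condition {calibrator!r} not among groups {conditions}"
        )
    for g in targets + references:
        if g not in ct.gene_ids:
            raise ValidationError(f"gene {g!r} not in the Ct table")

    frame = ct.to_frame()
    labels = ct.sample_groups()

    def log2_base(gene: str) -> float:
        if efficiencies is None:
            return 1.0
        return float(np.log2(efficiencies.base(gene)))

    # per-sample dCt on an efficiency-weighted log2 scale:
    #   dct_j = b_t * Ct_t[j] - mean_r(b_r * Ct_r[j])
    # with b = 1 for the classic method.
    ref_w = np.array(
        [[log2_base(r) * v for v in frame.loc[r]] for r in references]
    )
    ref_combined = ref_w.mean(axis=0)

    rows = []
    for t in targets:
        dct_sample = log2_base(t) * frame.loc[t].to_numpy() - ref_combined
        dct_by_cond = {}
        sd_by_cond = {}
        for c in conditions:
            vals = dct_sample[labels == c]
            dct_by_cond[c] = float(vals.mean())
            sd_by_cond[c] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        for c in conditions:
            ddct = dct_by_cond[c] - dct_by_cond[calibrator]
            rows.append(
                {
                    "target": t,
                    "condition": c,
                    "dct": dct_by_cond[c],
                    "dct_sd": sd_by_cond[c],
                    "ddct": ddct,
                    "fold": float(2.0 ** -ddct),
                }
            )
    return DdctResult(
        table=pd.DataFrame(rows),
        references=tuple(references),
        calibrator=calibrator,
    )


def concordance(
    ddct_results: Mapping[str, DdctResult],
    expr_fc: Union[pd.DataFrame, pd.Series, Mapping[str, float]],
) -> ConcordanceReport:
    """Rank reference genes by closeness of their qPCR folds to expression folds.

    *ddct_results* maps reference-gene label -> the :class:`DdctResult`
    obtained using that reference.  *expr_fc* gives the expression-matrix
    fold changes: a targets x conditions DataFrame, or a Series/dict keyed by
    target when there is a single non-calibrator condition.  All fold changes
    must be positive; the calibrator column (fold 1) is ignored.
    """
    if not ddct_results:
        raise ValidationError("no ddCt results supplied")
    distances = {}
    for ref, res in ddct_results.items():
        folds = res.folds().drop(columns=[res.calibrator])
        if isinstance(expr_fc, pd.DataFrame):
            expected = expr_fc
        else:
            expected = pd.Series(dict(expr_fc), dtype=float)
            if folds.shape[1] != 1:
                raise ValidationError(
                    "a Series/dict of expression folds needs exactly one "
                    "non-calibrator condition"
                )
            expected = expected.to_frame(folds.columns[0])
        missing = set(folds.index) ^ set(expected.index)
        if missing:
            raise ValidationError(f"target mismatch with expression folds: {sorted(missing)}")
        expected = expected.reindex(index=folds.index, columns=folds.columns)
        if expected.isna().any().any() or (expected <= 0).any().any():
            raise ValidationError("expression fold changes must cover all "
                                  "targets/conditions and be positive")
        diff = np.abs(np.log2(folds.to_numpy()) - np.log2(expected.to_numpy()))
        distances[ref] = float(diff.mean())
    order = sorted(distances, key=lambda r: (distances[r], r))
    table = pd.DataFrame(
        {
            "distance": [distances[r] for r in order],
            "rank": np.arange(1, len(order) + 1),
        },
        index=order,
    )
    return ConcordanceReport(table=table)
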