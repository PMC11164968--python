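"""Transcriptome-based screening of candidate reference genes.

The screening funnel: in each of several expression datasets (gene x sample
abundance matrices with condition labels), flag genes that are not
differentially expressed; intersect the flagged sets across datasets;
drop genes with any zero abundance; and rank the survivors by abundance in a
chosen reference sample to keep the top N as qPCR candidates.

How "non-differentially expressed" is decided upstream varies by study; this
module accepts externally derived gene lists verbatim and also provides a
simple self-contained criterion (bounded max pairwise |log2 fold change| of
condition means plus bounded coefficient of variation).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data_model import ParseError, ValidationError, _check_unique

__all__ = [
    "ExpressionSet",
    "CandidateReport",
    "read_expression_set",
    "flag_non_de",
    "intersect_candidates",
    "rank_select_top",
    "screen_candidates",
]


@dataclass(frozen=True)
class ExpressionSet:
    """Gene x sample abundance matrix (TPM/FPKM-like) with condition labels."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    x: np.ndarray
    conditions: Mapping[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        x = np.asarray(self.x, dtype=float)
        if x.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("abundance matrix shape does not match ids")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValidationError("abundances must be finite and >= 0")
        object.__setattr__(self, "x", x)
        conditions = {str(k): str(v) for k, v in dict(self.conditions).items()}
        missing = [s for s in self.sample_ids if s not in conditions]
        if missing:
            raise ValidationError(f"samples without a condition: {missing}")
        if not conditions:
            raise ValidationError("conditions must be non-empty")
        object.__setattr__(self, "conditions", conditions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def condition_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def read_expression_set(path: Union[str, Path], name: str = "") -> ExpressionSet:
    """Read a gene x sample abundance CSV/TSV.

    Layout mirrors the wide Ct dialect: header row of sample ids (first
    column ``gene``), a second row labelled ``condition`` carrying the
    condition of each sample, then one row per gene.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or len(df) < 2:
        raise ParseError(f"{path}: expected sample columns plus a condition row")
    samples = [str(c) for c in df.columns[1:]]
    if df.iloc[0, 0].strip().lower() != "condition":
        raise ParseError(f"{path}: second row must be the 'condition' row")
    conditions = {s: str(v) for s, v in zip(samples, df.iloc[0, 1:])}
    body = df.iloc[1:]
    genes = [str(g) for g in body.iloc[:, 0]]
    try:
        x = body.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance: {exc}") from None
    return ExpressionSet(tuple(genes), tuple(samples), x, conditions,
                         name=name or path.stem)


@dataclass(frozen=True)
class CandidateReport:
    """Result of the screening funnel, with per-stage set sizes."""

    per_dataset: Mapping[str, frozenset[str]]
    intersection: frozenset[str]
    nonzero_filtered: frozenset[str]
    final: tuple[str, ...]

    @property
    def funnel_sizes(self) -> tuple[int, ...]:
        """Sizes: one per dataset, then intersection, filtered, final."""
        return (
            *(len(s) for s in self.per_dataset.values()),
            len(self.intersection),
            len(self.nonzero_filtered),
            len(self.final),
        )

    def check_monotone(self) -> None:
        if not (
            len(self.final)
            <= len(self.nonzero_filtered)
            <= len(self.intersection)
            <= min(len(s) for s in self.per_dataset.values())
        ):
            raise ValidationError("candidate funnel is not monotone")


def flag_non_de(
    es: ExpressionSet,
    max_abs_log2fc: float = 1.0,
    max_cv: float = 0.5,
    pseudocount: float = 1.0,
) -> frozenset[str]:
    """Flag genes that look non-differentially expressed in one dataset.

    A gene passes when the largest pairwise |log2 fold change| between
    condition means (after adding *pseudocount*) is at most *max_abs_log2fc*
    and its across-sample coefficient of variation (SD / mean on the raw
    scale) is at most *max_cv*.  A constant gene always passes.
    """
    if es.x.size == 0:
        raise ValidationError("empty expression matrix")
    labels = np.array([es.conditions[s] for s in es.sample_ids])
    cond_order = list(dict.fromkeys(labels))
    means = np.column_stack(
        [es.x[:, labels == c].mean(axis=1) for c in cond_order]
    )
    logm = np.log2(means + pseudocount)
    max_fc = logm.max(axis=1) - logm.min(axis=1)

    mean_all = es.x.mean(axis=1)
    sd_all = es.x.std(axis=1, ddof=1) if es.x.shape[1] > 1 else np.zeros(len(es.gene_ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(sd_all == 0, 0.0, sd_all / np.where(mean_all == 0, np.nan, mean_all))
    cv = np.where(np.isnan(cv), np.inf, cv)

    keep = (max_fc <= max_abs_log2fc) & (cv <= max_cv)
    return frozenset(g for g, k in zip(es.gene_ids, keep) if k)


def intersect_candidates(
    sets: Sequence[Iterable[str]],
    es_list: Optional[Sequence[ExpressionSet]] = None,
    require_nonzero: bool = False,
) -> frozenset[str]:
    """Intersect per-dataset gene sets, optionally dropping zero-expression genes.

    With *require_nonzero*, any gene whose abundance is zero in at least one
    sample of at least one dataset in *es_list* is removed.
    """
    sets = [frozenset(s) for s in sets]
    if not sets:
        raise ValidationError("need at least one gene set")
    result = frozenset.intersection(*sets)
    if require_nonzero:
        if not es_list:
            raise ValidationError("require_nonzero needs the expression sets")
        for es in es_list:
            zero = {
                g
                for i, g in enumerate(es.gene_ids)
                if g in result and np.any(es.x[i] == 0)
            }
            result -= zero
    return result


def rank_select_top(
    candidates: Iterable[str],
    es: ExpressionSet,
    reference_sample: str,
    n: int = 12,
) -> tuple[str, ...]:
    """Keep the *n* candidates most abundant in *reference_sample*.

    Sorted descending by abundance (ties broken by gene id); fewer than *n*
    candidates are returned as-is, never padded.
    """
    if reference_sample not in es.sample_ids:
        raise ValidationError(
            f"reference sample {reference_sample!r} not in dataset {es.name!r}"
        )
    j = es.sample_ids.index(reference_sample)
    abundance = {g: es.x[es.gene_ids.index(g), j] for g in candidates}
    ordered = sorted(abundance, key=lambda g: (-abundance[g], g))
    return tuple(ordered[:n])


def screen_candidates(
    es_list: Sequence[ExpressionSet],
    reference_sample: str,
    reference_dataset: int = 0,
    n: int = 12,
    max_abs_log2fc: float = 1.0,
    max_cv: float = 0.5,
    pseudocount: float = 1.0,
    non_de_sets: Optional[Mapping[str, Iterable[str]]] = None,
) -> CandidateReport:
    """Run the whole funnel over several expression datasets.

    Per-dataset non-DE sets come from *non_de_sets* when supplied (e.g. from
    an external differential-expression pipeline) and from
    :func:`flag_non_de` otherwise.  The final ranking uses
    *reference_sample* in ``es_list[reference_dataset]``.
    """
    if not es_list:
        raise ValidationError("need at least one expression dataset")
    names = [es.name or f"dataset{i + 1}" for i, es in enumerate(es_list)]
    per_dataset: dict[str, frozenset[str]] = {}
    for name, es in zip(names, es_list):
        if non_de_sets is not None and name in non_de_sets:
            per_dataset[name] = frozenset(non_de_sets[name])
        else:
            per_dataset[name] = flag_non_de(
                es, max_abs_log2fc=max_abs_log2fc, max_cv=max_cv,
                pseudocount=pseudocount,
            )
    intersection = intersect_candidates(list(per_dataset.values()))
    filtered = intersect_candidates(
        [intersection], es_list=es_list, require_nonzero=True
    )
    final = rank_select_top(
        filtered, es_list[reference_dataset], reference_sample, n=n
    )
    report = CandidateReport(
        per_dataset=per_dataset,
        intersection=intersection,
        nonzero_filtered=filtered,
        final=final,
    )
    report.check_monotone()
    return report
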