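"""Core domain types for qRT-PCR stability analysis.

The central objects are :class:`CtTable` (quantification-cycle values for a
panel of candidate reference genes measured across samples that belong to
experimental groups) and :class:`QuantityTable` (the same data transformed to
linear-scale relative quantities ``Q = B**(Ct_min - Ct)``, the input expected
by geNorm- and NormFinder-style algorithms).

Matrices are oriented genes-in-rows x samples-in-columns everywhere.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "RefstabError",
    "ParseError",
    "ValidationError",
    "EfficiencyWarning",
    "CtTable",
    "QuantityTable",
    "EfficiencyMap",
    "read_ct_table",
    "write_ct_table",
    "ct_to_quantity",
    "as_quantity_frame",
]


class RefstabError(Exception):
    """Base class for errors raised by this package."""


class ParseError(RefstabError):
    """A tabular input file could not be interpreted."""


class ValidationError(RefstabError):
    """A domain object violates one of its invariants."""


class EfficiencyWarning(UserWarning):
    """An amplification efficiency falls outside the usual QC range."""


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    if not ids:
        raise ValidationError(f"no {what} ids given")
    return ids


@dataclass(frozen=True)
class CtTable:
    """Genes x samples matrix of quantification-cycle (Ct) values.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    ct
        Array of shape ``(n_genes, n_samples)``.  All values must be finite
        and strictly positive; missing values are rejected rather than
        imputed because every downstream statistic would silently change.
    groups
        Map from sample id to experimental-group label.  Every sample must
        have exactly one label.
    tech_rep_counts
        Optional record of how many technical replicates were averaged into
        each cell when the table was read from a long-format file.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    ct: np.ndarray
    groups: Mapping[str, str]
    tech_rep_counts: Optional[Mapping[tuple[str, str], int]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        ct = np.asarray(self.ct, dtype=float)
        if ct.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"ct matrix shape {ct.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(ct)):
            i, j = np.argwhere(~np.isfinite(ct))[0]
            raise ValidationError(
                f"non-finite Ct for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(ct <= 0):
            i, j = np.argwhere(ct <= 0)[0]
            raise ValidationError(
                f"non-positive Ct for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        object.__setattr__(self, "ct", ct)
        groups = {str(k): str(v) for k, v in dict(self.groups).items()}
        missing = [s for s in self.sample_ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        object.__setattr__(self, "groups", groups)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_labels(self) -> tuple[str, ...]:
        """Group labels in order of first appearance along the sample axis."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def sample_groups(self) -> np.ndarray:
        """Per-column group label, aligned with ``sample_ids``."""
        return np.array([self.groups[s] for s in self.sample_ids])

    def subset_genes(self, genes: Sequence[str]) -> "CtTable":
        idx = [self.gene_ids.index(g) for g in genes]
        return CtTable(tuple(genes), self.sample_ids, self.ct[idx], self.groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ct, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, s in enumerate(self.sample_ids):
                rows.append((g, s, self.groups[s], self.ct[i, j]))
        return pd.DataFrame(rows, columns=["gene", "sample", "group", "ct"])


@dataclass(frozen=True)
class QuantityTable:
    """Genes x samples matrix of relative quantities Q in (0, 1].

    Per gene the maximum quantity over samples is 1: each gene is expressed
    relative to its own most-expressed sample.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    q: np.ndarray
    groups: Mapping[str, str]
    #: False when quantities were computed against minima pooled over a wider
    #: sample series, in which case the per-gene max may fall below 1.
    unit_max: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        q = np.asarray(self.q, dtype=float)
        if q.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"q matrix shape {q.shape} does not match id lists"
            )
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValidationError("all quantities must be finite and > 0")
        rowmax = q.max(axis=1)
        if self.unit_max and np.any(np.abs(rowmax - 1.0) > 1e-12):
            bad = self.gene_ids[int(np.argmax(np.abs(rowmax - 1.0)))]
            raise ValidationError(
                f"per-gene maximum quantity must be 1 (gene {bad!r})"
            )
        if np.any(rowmax > 1.0 + 1e-12):
            raise ValidationError("quantities must not exceed 1")
        object.__setattr__(self, "q", q)
        groups = {str(k): str(v) for k, v in dict(self.groups).items()}
        missing = [s for s in self.sample_ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        object.__setattr__(self, "groups", groups)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def sample_groups(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def log2(self) -> pd.DataFrame:
        return np.log2(self.to_frame())


# geNorm / NormFinder / aggregation functions accept either a QuantityTable or
# a bare genes x samples DataFrame of positive values (handy for worked
# examples where the per-gene max need not be 1 -- every statistic downstream
# is invariant to per-gene rescaling).
QuantityLike = Union[QuantityTable, pd.DataFrame]


def as_quantity_frame(q: QuantityLike) -> pd.DataFrame:
    """Coerce a QuantityTable or DataFrame to a positive genes x samples frame."""
    if isinstance(q, QuantityTable):
        return q.to_frame()
    frame = pd.DataFrame(q).astype(float)
    if not np.all(np.isfinite(frame.to_numpy())) or np.any(frame.to_numpy() <= 0):
        raise ValidationError("quantities must be finite and strictly positive")
    return frame


@dataclass(frozen=True)
class EfficiencyMap:
    """Per-gene amplification efficiency stored as a fraction.

    E = 1.0 means perfect doubling (100%); the per-cycle fold change is
    B = 1 + E.  Values outside the conventional QC window [0.9, 1.1] are
    accepted but flagged with an :class:`EfficiencyWarning`.
    """

    efficiencies: Mapping[str, float]

    def __post_init__(self) -> None:
        eff = {str(k): float(v) for k, v in dict(self.efficiencies).items()}
        for gene, e in eff.items():
            if not (0.0 < e <= 1.5):
                raise ValidationError(
                    f"efficiency for {gene!r} is {e}; must be in (0, 1.5]"
                )
            if not (0.9 <= e <= 1.1):
                warnings.warn(
                    f"efficiency for {gene!r} is {e * 100:.1f}%, outside the "
                    "usual 90-110% range",
                    EfficiencyWarning,
                    stacklevel=2,
                )
        object.__setattr__(self, "efficiencies", eff)

    def __getitem__(self, gene: str) -> float:
        return self.efficiencies[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.efficiencies

    def base(self, gene: str) -> float:
        """Per-cycle fold factor B = 1 + E for a gene."""
        return 1.0 + self.efficiencies[gene]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read {path}: {exc}") from exc


def _parse_ct(value: str, gene: str, sample: str, path: Path) -> float:
    if value.strip() == "":
        raise ParseError(
            f"{path}: missing Ct for gene {gene!r}, sample {sample!r}"
        )
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric Ct {value!r} for gene {gene!r}, "
            f"sample {sample!r}"
        ) from None


def read_ct_table(
    path: Union[str, Path],
    format: str = "wide",
    groups: Optional[Union[str, Path, Mapping[str, str]]] = None,
) -> CtTable:
    """Read a Ct table from a CSV/TSV file.

    Two dialects are supported:

    * ``wide`` -- first column ``gene``, remaining columns one per sample.
      Group labels come either from an optional second header row whose first
      cell is ``group``, or from a two-column sidecar (``sample,group``)
      passed via *groups*.
    * ``long`` -- tidy columns ``gene,sample,group,ct`` (``group`` may be
      omitted when *groups* is supplied).  Repeated (gene, sample) rows are
      treated as technical replicates and collapsed by their arithmetic mean
      on the Ct scale, with the replicate count recorded.
    """
    path = Path(path)
    group_map: Optional[dict[str, str]] = None
    if groups is not None:
        if isinstance(groups, (str, Path)):
            gdf = _read_table(groups)
            if gdf.shape[1] < 2:
                raise ParseError(f"{groups}: group sidecar needs 2 columns")
            group_map = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
        else:
            group_map = {str(k): str(v) for k, v in groups.items()}

    if format == "long":
        return _read_long(path, group_map)
    if format == "wide":
        return _read_wide(path, group_map)
    raise ValueError(f"unknown format {format!r}; use 'wide' or 'long'")


def _read_long(path: Path, group_map: Optional[dict[str, str]]) -> CtTable:
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("gene", "sample", "ct"):
        if required not in cols:
            raise ParseError(f"{path}: long format needs a {required!r} column")
    has_group_col = "group" in cols
    if not has_group_col and group_map is None:
        raise ParseError(
            f"{path}: no 'group' column and no group sidecar supplied"
        )

    values: dict[tuple[str, str], list[float]] = {}
    genes: list[str] = []
    samples: list[str] = []
    inferred_groups: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene = str(getattr(row, cols["gene"]))
        sample = str(getattr(row, cols["sample"]))
        ct = _parse_ct(str(getattr(row, cols["ct"])), gene, sample, path)
        if has_group_col:
            g = str(getattr(row, cols["group"]))
            prev = inferred_groups.setdefault(sample, g)
            if prev != g:
                raise ParseError(
                    f"{path}: sample {sample!r} assigned to both group "
                    f"{prev!r} and {g!r}"
                )
        if gene not in genes:
            genes.append(gene)
        if sample not in samples:
            samples.append(sample)
        values.setdefault((gene, sample), []).append(ct)

    final_groups = group_map if group_map is not None else inferred_groups
    ct = np.full((len(genes), len(samples)), np.nan)
    counts: dict[tuple[str, str], int] = {}
    for (gene, sample), reps in values.items():
        ct[genes.index(gene), samples.index(sample)] = float(np.mean(reps))
        counts[(gene, sample)] = len(reps)
    if np.any(np.isnan(ct)):
        i, j = np.argwhere(np.isnan(ct))[0]
        raise ParseError(
            f"{path}: no Ct for gene {genes[i]!r}, sample {samples[j]!r}"
        )
    return CtTable(tuple(genes), tuple(samples), ct, final_groups, counts)


def _read_wide(path: Path, group_map: Optional[dict[str, str]]) -> CtTable:
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: wide format needs a gene column + samples")
    samples = [str(c) for c in df.columns[1:]]
    first_col = df.iloc[:, 0].astype(str)
    if len(df) and first_col.iloc[0].strip().lower() == "group":
        row_groups = {s: str(v) for s, v in zip(samples, df.iloc[0, 1:])}
        df = df.iloc[1:].reset_index(drop=True)
        if group_map is None:
            group_map = row_groups
    if group_map is None:
        raise ParseError(
            f"{path}: no 'group' header row and no group sidecar supplied"
        )
    genes = [str(g) for g in df.iloc[:, 0]]
    ct = np.empty((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        for j, sample in enumerate(samples):
            ct[i, j] = _parse_ct(str(df.iloc[i, j + 1]), gene, sample, path)
    return CtTable(tuple(genes), tuple(samples), ct, group_map)


def write_ct_table(table: CtTable, path: Union[str, Path], format: str = "wide") -> None:
    """Write a CtTable as CSV/TSV in the wide or long dialect.

    The wide dialect includes the ``group`` header row so the file round-trips
    through :func:`read_ct_table` without a sidecar.  Values are written with
    :func:`repr`-level precision so round-trips are bit-exact.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w", encoding="utf-8") as fh:
        if format == "wide":
            fh.write(sep.join(["gene", *table.sample_ids]) + "\n")
            fh.write(
                sep.join(["group", *(table.groups[s] for s in table.sample_ids)])
                + "\n"
            )
            for i, gene in enumerate(table.gene_ids):
                fh.write(
                    sep.join([gene, *(repr(float(v)) for v in table.ct[i])]) + "\n"
                )
        elif format == "long":
            fh.write(sep.join(["gene", "sample", "group", "ct"]) + "\n")
            for i, gene in enumerate(table.gene_ids):
                for j, sample in enumerate(table.sample_ids):
                    fh.write(
                        sep.join(
                            [gene, sample, table.groups[sample],
                             repr(float(table.ct[i, j]))]
                        )
                        + "\n"
                    )
        else:
            raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# Ct -> relative quantity
# --------------------------------------------------------------------------

def ct_to_quantity(
    table: CtTable,
    efficiencies: Optional[EfficiencyMap] = None,
    assume_perfect: bool = False,
    ct_min: Optional[Mapping[str, float]] = None,
) -> QuantityTable:
    """Transform Ct values to relative quantities ``Q = B**(Ct_min - Ct)``.

    ``B`` is the per-cycle fold factor ``1 + E`` for each gene's amplification
    efficiency E, or exactly 2 for every gene when *assume_perfect* is set
    (the usual convention when all efficiencies are close to 100%).
    ``Ct_min`` is each gene's minimum Ct over the samples in the table, so the
    most-expressed sample of every gene gets Q = 1; pass *ct_min* to use
    minima pooled over a larger sample series instead.
    """
    if not assume_perfect and efficiencies is None:
        raise ValidationError(
            "either supply an EfficiencyMap or set assume_perfect=True"
        )
    bases = np.empty(table.n_genes)
    for i, gene in enumerate(table.gene_ids):
        if assume_perfect:
            bases[i] = 2.0
        else:
            assert efficiencies is not None
            if gene not in efficiencies:
                raise ValidationError(f"no efficiency for gene {gene!r}")
            bases[i] = efficiencies.base(gene)
    if ct_min is None:
        minima = table.ct.min(axis=1)
    else:
        minima = np.array([float(ct_min[g]) for g in table.gene_ids])
        per_table = table.ct.min(axis=1)
        if np.any(minima > per_table + 1e-9):
            raise ValidationError(
                "supplied ct_min exceeds an observed Ct; pooled minima must "
                "be <= the per-table minima"
            )
    q = bases[:, None] ** (minima[:, None] - table.ct)
    # force the per-gene max to exactly 1 (it is 1 analytically; floating
    # point exponentiation can leave it at 1 +/- 1 ulp)
    if ct_min is None:
        q = q / q.max(axis=1, keepdims=True)
    return QuantityTable(
        table.gene_ids, table.sample_ids, q, table.groups, unit_max=ct_min is None
    )
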