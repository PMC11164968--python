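"""Synthetic qPCR and expression data with known ground truth.

Every analysis stage in this package can be exercised without any wet-lab
data: this module generates Ct matrices, serial-dilution curves and
expression matrices from explicit generative models and hands back the
parameters it drew from, so recovery can be checked.

Ct model (cycles):

    ct[i, j] = mu_i + s_j + delta_{i, g(j)} + N(0, sigma_i**2)

* ``mu_i``     per-gene baseline Ct (expression level of the gene),
* ``s_j``      per-sample loading shift shared by all genes -- differences in
               cDNA input that good normalization must cancel,
* ``delta_ig`` per-gene x group condition effect -- the *instability* a
               stability algorithm should detect,
* ``sigma_i``  per-gene noise SD.

Because Ct is a log2-scale quantity, Gaussian noise here is multiplicative
noise on transcript abundance, which is exactly the error model geNorm and
NormFinder assume.  The true instability of a gene is

    sqrt( mean over groups of delta_ig**2  +  sigma_i**2 )

Dilution model: Ct rises by log10(dilution_factor) / log10(1 + E) cycles per
dilution step (2 cycles per 4-fold step at perfect efficiency).

Scenario presets mirror a typical fish reference-gene study design: panels of
12 candidate genes measured over 10 tissues x 3 biological replicates, 10
developmental stages x 3, or a 2-arm treatment x 3.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .candidates import ExpressionSet
from .data_model import CtTable, ValidationError

__all__ = [
    "CtSimSpec",
    "CtTruth",
    "DilutionSimSpec",
    "ExpressionDesign",
    "simulate_ct",
    "simulate_dilution",
    "simulate_expression",
    "expand_technical_replicates",
    "preset_ct_spec",
    "PRESET_GROUPS",
    "demo_candidate_funnel",
]


@dataclass(frozen=True)
class CtSimSpec:
    """Parameters of the Ct generative model.

    ``loading`` (explicit per-sample shifts) overrides ``loading_sd`` (draw
    shifts from N(0, loading_sd**2)).  ``delta`` is an explicit gene x group
    effect matrix; ``delta_scale`` draws delta_ig ~ N(0, delta_scale_i**2)
    instead.  Omitting both gives a gene no condition effect.
    """

    gene_ids: tuple[str, ...]
    group_sizes: Mapping[str, int]            # ordered group label -> n samples
    mu: tuple[float, ...]                     # baseline Ct per gene, cycles
    sigma: tuple[float, ...]                  # noise SD per gene, cycles
    seed: int = 0
    loading_sd: float = 0.2                   # cycles
    loading: Optional[tuple[float, ...]] = None
    delta: Optional[tuple[tuple[float, ...], ...]] = None
    delta_scale: Optional[tuple[float, ...]] = None
    tau: float = 0.0                          # technical-replicate SD, cycles

    def __post_init__(self) -> None:
        k = len(self.gene_ids)
        if k == 0 or not self.group_sizes:
            raise ValidationError("need at least one gene and one group")
        if len(self.mu) != k or len(self.sigma) != k:
            raise ValidationError("mu and sigma must have one entry per gene")
        if any(s < 0 for s in self.sigma) or self.tau < 0 or self.loading_sd < 0:
            raise ValidationError("sigma, tau and loading_sd must be >= 0")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValidationError("every group needs >= 1 sample")
        n = sum(self.group_sizes.values())
        if self.loading is not None and len(self.loading) != n:
            raise ValidationError("loading must have one entry per sample")
        g = len(self.group_sizes)
        if self.delta is not None and (
            len(self.delta) != k or any(len(row) != g for row in self.delta)
        ):
            raise ValidationError("delta must be genes x groups")
        if self.delta_scale is not None and len(self.delta_scale) != k:
            raise ValidationError("delta_scale must have one entry per gene")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class CtTruth:
    """Realized generator parameters for a simulated Ct table."""

    spec: CtSimSpec
    loading: np.ndarray          # per sample
    delta: np.ndarray            # genes x groups

    def true_instability(self) -> pd.Series:
        """sqrt(mean over groups of delta**2 + sigma**2) per gene."""
        sigma = np.asarray(self.spec.sigma)
        inst = np.sqrt((self.delta ** 2).mean(axis=1) + sigma ** 2)
        return pd.Series(inst, index=list(self.spec.gene_ids), name="instability")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.spec.gene_ids),
            "group_sizes": dict(self.spec.group_sizes),
            "mu": list(self.spec.mu),
            "sigma": list(self.spec.sigma),
            "seed": self.spec.seed,
            "loading": self.loading.tolist(),
            "delta": self.delta.tolist(),
            "true_instability": self.true_instability().tolist(),
        }


def simulate_ct(
    spec: CtSimSpec, rng: Optional[np.random.Generator] = None
) -> tuple[CtTable, CtTruth]:
    """Draw a Ct table from the generative model.

    Deterministic for a fixed spec (the seed lives in the spec); pass *rng*
    to draw several replicate tables from one stream.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    genes = spec.gene_ids
    group_order = list(spec.group_sizes)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for g in group_order:
        for r in range(spec.group_sizes[g]):
            sid = f"{g}_r{r + 1}"
            sample_ids.append(sid)
            groups[sid] = g
    n = len(sample_ids)
    k = len(genes)

    if spec.loading is not None:
        loading = np.asarray(spec.loading, dtype=float)
    else:
        loading = rng.normal(0.0, spec.loading_sd, size=n) if spec.loading_sd > 0 else np.zeros(n)
    if spec.delta is not None:
        delta = np.asarray(spec.delta, dtype=float)
    elif spec.delta_scale is not None:
        scale = np.asarray(spec.delta_scale, dtype=float)
        delta = rng.normal(0.0, 1.0, size=(k, len(group_order))) * scale[:, None]
    else:
        delta = np.zeros((k, len(group_order)))

    gidx = np.array([group_order.index(groups[s]) for s in sample_ids])
    mu = np.asarray(spec.mu, dtype=float)
    sigma = np.asarray(spec.sigma, dtype=float)
    noise = rng.normal(0.0, 1.0, size=(k, n)) * sigma[:, None]
    ct = mu[:, None] + loading[None, :] + delta[:, gidx] + noise
    table = CtTable(genes, tuple(sample_ids), ct, groups)
    return table, CtTruth(spec=spec, loading=loading, delta=delta)


def expand_technical_replicates(
    table: CtTable, tau: float, n_reps: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Long-format frame with *n_reps* technical replicates per cell.

    Each replicate is the cell's Ct plus N(0, tau**2) pipetting noise; useful
    for exercising the reader's replicate averaging.
    """
    if tau < 0 or n_reps < 1:
        raise ValidationError("tau >= 0 and n_reps >= 1 required")
    rng = np.random.default_rng(seed)
    rows = []
    for i, gene in enumerate(table.gene_ids):
        for j, sample in enumerate(table.sample_ids):
            for _ in range(n_reps):
                rows.append(
                    (gene, sample, table.groups[sample],
                     table.ct[i, j] + rng.normal(0.0, tau))
                )
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "ct"])


@dataclass(frozen=True)
class DilutionSimSpec:
    """Serial-dilution series with known true efficiency."""

    efficiency: float            # true E, fraction
    top_ct: float = 18.0         # Ct of the most concentrated point
    dilution_factor: float = 4.0
    n_points: int = 8
    noise_sd: float = 0.0        # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValidationError("dilution factor must be > 1")
        if self.n_points < 3:
            raise ValidationError("need >= 3 dilution points")
        if not (0 < self.efficiency <= 1.5):
            raise ValidationError("efficiency must be in (0, 1.5]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_dilution(spec: DilutionSimSpec) -> pd.DataFrame:
    """Simulate a dilution series as a (log10_conc, ct) frame.

    Concentrations are log10 relative to the top point (0, -log10(f), ...);
    Ct climbs log10(f)/log10(1+E) cycles per step plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.arange(spec.n_points)
    step = np.log10(spec.dilution_factor) / np.log10(1.0 + spec.efficiency)
    ct = spec.top_ct + p * step
    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return pd.DataFrame(
        {"log10_conc": -p * np.log10(spec.dilution_factor), "ct": ct}
    )


@dataclass(frozen=True)
class ExpressionDesign:
    """One expression dataset: a name and condition -> n-samples map."""

    name: str
    conditions: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValidationError("conditions must be non-empty")


def simulate_expression(
    gene_ids: Sequence[str],
    designs: Sequence[ExpressionDesign],
    planted_stable: Sequence[str] = (),
    seed: int = 0,
    stable_noise_sd: float = 0.05,       # log2 units
    unstable_noise_sd: float = 0.2,
    de_effect_range: tuple[float, float] = (1.5, 3.0),   # |log2| effect per condition
) -> list[ExpressionSet]:
    """Log-normal expression matrices with planted stable genes.

    Genes in *planted_stable* receive no condition effect and only small
    multiplicative noise, so they satisfy the built-in non-DE criterion in
    every generated dataset and are never zero.  All other genes get an
    independent random condition effect of magnitude drawn from
    *de_effect_range* (log2 units, random sign) per condition.
    """
    planted = set(planted_stable)
    unknown = planted - set(gene_ids)
    if unknown:
        raise ValidationError(f"planted_stable not in gene_ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base_log2 = rng.normal(6.0, 1.5, size=len(gene_ids))
    out: list[ExpressionSet] = []
    lo, hi = de_effect_range
    for design in designs:
        cond_order = list(design.conditions)
        sample_ids: list[str] = []
        conditions: dict[str, str] = {}
        for c in cond_order:
            for r in range(design.conditions[c]):
                sid = f"{design.name}_{c}_r{r + 1}"
                sample_ids.append(sid)
                conditions[sid] = c
        cidx = np.array([cond_order.index(conditions[s]) for s in sample_ids])
        k, n = len(gene_ids), len(sample_ids)
        effect = np.zeros((k, len(cond_order)))
        noise_sd = np.empty(k)
        for i, g in enumerate(gene_ids):
            if g in planted:
                noise_sd[i] = stable_noise_sd
            else:
                noise_sd[i] = unstable_noise_sd
                effect[i] = rng.uniform(lo, hi, size=len(cond_order)) * rng.choice(
                    [-1.0, 1.0], size=len(cond_order)
                )
        log2x = (
            base_log2[:, None]
            + effect[:, cidx]
            + rng.normal(0.0, 1.0, size=(k, n)) * noise_sd[:, None]
        )
        out.append(
            ExpressionSet(
                tuple(gene_ids), tuple(sample_ids), 2.0 ** log2x, conditions,
                name=design.name,
            )
        )
    return out


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

PRESET_GROUPS: dict[str, dict[str, int]] = {
    "tissues": {f"tissue{t:02d}": 3 for t in range(1, 11)},
    "stages": {f"stage{t:02d}": 3 for t in range(1, 11)},
    "treatment": {"control": 3, "treated": 3},
}

_N_PRESET_GENES = 12


def preset_ct_spec(
    preset: str, seed: int = 0, scenario: str = "graded"
) -> CtSimSpec:
    """Ready-made simulation specs for the three study designs.

    * ``graded`` -- per-gene noise SDs graded 0.05..0.6 cycles and condition
      effect scales graded 0..0.5 cycles, so true instability increases
      steadily from the first gene (G01, most stable) to the last.
    * ``planted_winner`` -- one clearly stable gene (sigma 0.05 cycles, no
      condition effect) among eleven noisy ones (sigma 0.3..0.6).

    Baseline Ct values are drawn once per seed from U(18, 30) cycles, the
    range typical of moderately to highly expressed transcripts.
    """
    if preset not in PRESET_GROUPS:
        raise ValidationError(f"unknown preset {preset!r}; use {sorted(PRESET_GROUPS)}")
    genes = tuple(f"G{i:02d}" for i in range(1, _N_PRESET_GENES + 1))
    rng = np.random.default_rng(seed)
    mu = tuple(rng.uniform(18.0, 30.0, size=_N_PRESET_GENES))
    if scenario == "graded":
        sigma = tuple(np.linspace(0.05, 0.6, _N_PRESET_GENES))
        delta_scale = tuple(np.linspace(0.0, 0.5, _N_PRESET_GENES))
    elif scenario == "planted_winner":
        sigma = (0.05, *np.linspace(0.3, 0.6, _N_PRESET_GENES - 1))
        delta_scale = None
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")
    return CtSimSpec(
        gene_ids=genes,
        group_sizes=PRESET_GROUPS[preset],
        mu=mu,
        sigma=sigma,
        delta_scale=delta_scale,
        loading_sd=0.2,
        seed=seed,
    )


def demo_candidate_funnel() -> tuple[list[ExpressionSet], dict]:
    """Small hand-built three-dataset screening fixture (synthetic).

    Designed so the funnel stage sizes are known by construction:
    per-dataset non-DE sets of sizes 5, 5 and 7, an intersection of 3 genes,
    one gene removed by the zero-abundance filter, and a final top-2 list.
    Returns the datasets plus a dict of the designed expectations.
    """
    genes = tuple(f"g{i:02d}" for i in range(1, 13))

    def build(name, non_de, n_per_cond, zero_cell=None, abundance=None):
        conds = ["c1", "c2"]
        sample_ids = [f"{name}_{c}_r{r+1}" for c in conds for r in range(n_per_cond)]
        conditions = {s: s.split("_")[1] for s in sample_ids}
        x = np.empty((len(genes), len(sample_ids)))
        for i, g in enumerate(genes):
            if g in non_de:
                x[i] = abundance.get(g, 20.0) if abundance else 20.0
            else:
                # strongly differential: 10 in c1 vs 80 in c2
                x[i] = [10.0 if conditions[s] == "c1" else 80.0 for s in sample_ids]
        if zero_cell is not None:
            gi, pattern = zero_cell
            x[genes.index(gi)] = pattern
        return ExpressionSet(genes, tuple(sample_ids), x, conditions, name=name)

    abundance = {"g01": 100.0, "g02": 50.0, "g03": 40.0, "g04": 30.0, "g05": 20.0}
    ds1 = build("tissues", {"g01", "g02", "g03", "g04", "g05"}, 2, abundance=abundance)
    ds2 = build("stages", {"g01", "g02", "g03", "g06", "g07"}, 2)
    # g03 carries one zero sample but stays non-DE: means 2.25 vs 2 and a
    # coefficient of variation just under 0.5
    ds3 = build(
        "treatment",
        {"g01", "g02", "g03", "g04", "g06", "g08", "g09"},
        4,
        zero_cell=("g03", [3.0, 3.0, 3.0, 0.0, 2.0, 2.0, 2.0, 2.0]),
    )
    expected = {
        "per_dataset_sizes": (5, 5, 7),
        "intersection": frozenset({"g01", "g02", "g03"}),
        "nonzero_filtered": frozenset({"g01", "g02"}),
        "final": ("g01", "g02"),
        "funnel_sizes": (5, 5, 7, 3, 2, 2),
        "reference_sample": "tissues_c1_r1",
        "top_n": 2,
    }
    return [ds1, ds2, ds3], expected
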