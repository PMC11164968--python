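# refstab

Choosing reference (housekeeping) genes for qRT-PCR is a statistics problem:
a target gene's measured expression is only as reliable as the stability of
the genes used to normalize it, and no single gene is stable across every
tissue, developmental stage or treatment. `refstab` implements the standard
stability toolbox used in reference-gene studies — for molecular biologists
running candidate panels on a qPCR instrument and for bioinformaticians who
pre-screen candidates from RNA-seq — as a tested, scriptable Python library
with a thin CLI.

## What it computes

Given a Ct table (genes × samples, with a sample → group map):

* **Relative quantities** — `Q = B^(Ct_min − Ct)` per gene, with base
  `B = 1 + E` from each gene's amplification efficiency (or `B = 2` when
  efficiencies are near 100%); the most-expressed sample of each gene gets
  `Q = 1`.
* **Standard curves** — OLS of Ct on log10 concentration over a dilution
  series; efficiency `E = 10^(−1/k) − 1` from the slope `k` (a perfectly
  doubling assay has `k ≈ −3.32`).
* **geNorm** — pairwise variation `V_jk = SD(log2 Q_j/Q_k)`, stability
  `M_j = mean_k V_jk`, stepwise exclusion of the worst gene, per-sample
  normalization factors `NF_n` (geometric means of the top-*n* genes), and
  the `V_n/n+1 < 0.15` rule for the optimal number of reference genes.
* **NormFinder-style decomposition** — on `y = log2 Q`, inter-group bias
  `d_ig` and intra-group variance `σ²_ig` (method-of-moments, corrected for
  shared per-sample loading effects), combined into
  `SV_i = mean_g sqrt(d_ig² + σ²_ig / n_g)`.
* **BestKeeper-style screening** — per-gene SD and CV of raw Ct (SD < 1
  cycle = conventionally stable), plus the geometric-mean index with
  per-gene Pearson correlations; flags the method as unsuitable when no gene
  passes.
* **Comparative ΔCt** — mean SD of pairwise Ct differences (identical to
  geNorm's M on perfect-efficiency quantities).
* **Comprehensive ranking** — RefFinder-style geometric mean of the four
  methods' ranks.
* **Candidate screening** — flag non-differentially expressed genes in
  several expression datasets, intersect, drop zero-expression genes, keep
  the top-N by abundance in a reference sample.
* **Validation** — `2^−ΔΔCt` fold changes of target genes under each
  candidate reference, scored for concordance against expression-matrix
  fold changes.

A synthetic-data module generates Ct tables
(`ct = mu_i + s_j + delta_ig + noise`), dilution series and expression
matrices with known ground truth, so every stage is testable end to end.

## Worked example

```python
import pandas as pd
import refstab as rs

# three genes over three samples: A and B move together, C is flat
q = pd.DataFrame([[1, 2, 4], [1, 2, 4], [1, 1, 1]],
                 index=["A", "B", "C"], columns=["s1", "s2", "s3"],
                 dtype=float)

print(rs.m_values(q).to_dict())
curve, recommended = rs.pairwise_v(q, ["A", "B", "C"])
print(curve, recommended)
print(rs.stepwise_ranking(q).order)
```

prints

```
{'A': 0.5, 'B': 0.5, 'C': 1.0}
((2, 0.33333333333333337),) None
('A', 'B', 'C')
```

A and B have `M = 0.5` (their mutual log-ratio is constant; only C disturbs
them) while the flat gene C — which ignores the shared 1→2→4 trend and is
therefore the *least* co-stable — gets `M = 1.0` and is excluded first.
`V_2/3 = 1/3` is above the 0.15 cutoff, so no gene count is recommended from
this tiny panel and screening should continue.

The same workflow from the shell:

```bash
refstab simulate --preset stages --seed 1 --out-dir out/sim
refstab stability --input out/sim/ct_wide.csv --out-dir out/stab
refstab all --preset stages --seed 1 --out-dir out/full
```

which writes per-method TSVs (`genorm.tsv`, `normfinder.tsv`,
`bestkeeper.tsv`, `deltact.tsv`), the V curve, the comprehensive ranking and
a JSON run summary whose config hash also appears in every TSV header.

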