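# Methods

This note records the statistical models behind `refstab`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Ct scale and relative quantities

Ct (quantification cycle) is a log-scale measurement: one cycle corresponds
to one doubling at 100% amplification efficiency. All analyses therefore
treat Gaussian noise on the Ct scale as the natural (multiplicative) qPCR
error model. The transformation to relative quantities is

    Q_ij = B_i^(Ctmin_i − Ct_ij),   B_i = 1 + E_i,

with `E_i` the gene's amplification efficiency as a fraction (1.0 = 100%);
`assume_perfect` forces `B = 2` for all genes, the standard shortcut when
efficiencies are near 100%. `Ctmin_i` is the gene's minimum Ct within the
analyzed table, so each gene's most expressed sample sits at `Q = 1`.
Minima may instead be supplied explicitly (pooled over a wider sample
series); quantities then fall below 1 and the container records that the
unit-max convention is relaxed. Every downstream statistic is invariant to
per-gene rescaling, so the choice affects reported Q values, not rankings.

Missing Ct values are rejected, never imputed: any imputation silently
changes every downstream dispersion statistic. Technical replicates are
averaged arithmetically on the Ct scale at read time (with the replicate
count retained); biological replicates stay distinct samples.

## Standard curves

Ct is regressed on log10 relative concentration (top dilution point at 0)
by ordinary least squares; efficiency follows from the slope via
`E = 10^(−1/k) − 1`. Quality thresholds — efficiency within [90%, 110%],
R² ≥ 0.98 — produce warnings, never failures, because practice treats them
as assay-quality descriptors rather than gates. The regression direction
matters for noisy data (regressing concentration on Ct would bias the
slope); with the relative-concentration x-axis, using dilution instead of
concentration flips only the sign convention, not |k|.

## geNorm

Pairwise variation `V_jk` is the sample SD (n−1 denominator throughout this
package) of `log2(Q_j / Q_k)` over samples; `M_j` is the mean of `V_jk`
over partners. Stepwise exclusion recomputes M on the surviving subset and
removes the highest-M gene each round; exact ties are broken by removing
the lexicographically smallest gene id, and the removal order is recorded
so runs are reproducible. The final two genes cannot be ranked against
each other (only their mutual ratio remains) and both receive rank 1.5,
which keeps the comprehensive ranking unbiased.

Normalization factors `NF_n` are per-sample geometric means of the top-n
genes' quantities; `V_n/n+1 = SD(log2 NF_n/NF_{n+1}))` is scanned from
n = 2 and the recommended gene count is the smallest n with V below the
cutoff (default 0.15). When no V qualifies the result is explicitly "none"
with a continue-screening advisory rather than the largest n. Log base 2
is used everywhere so M magnitudes are comparable to published geNorm
output. Note that appending a constant gene to a normalization set changes
`NF` geometrically (`NF_{n+1} = (NF_n^n)^{1/(n+1)}` times a constant), so
NF log-ratios shrink — it does not merely rescale NF.

## NormFinder-style decomposition

On `y = log2 Q` with genes i, groups g, samples j, the model is

    y_igj = alpha_i + beta_g + d_ig + b_gj + eps_igj,  eps ~ N(0, sigma2_ig),

where `b_gj` is the per-sample loading effect shared across genes. The
inter-group bias `d_ig` is estimated as the gene×group interaction
(cell mean − gene mean − group mean + grand mean, gene and grand means
weighting cells by group size), which makes the d values sum to zero over
genes within each group. For the intra-group variance, centering each
sample's column across the k genes removes `b_gj` but contaminates each
gene's residual with the panel average:

    Var(z_ig·) = sigma2_ig (1 − 2/k) + S_g / k²,  S_g = Σ_i sigma2_ig.

Solving via the group mean of the empirical variances `u_ig` gives the
unbiased method-of-moments estimator

    sigma2_ig = max(0, (u_ig − ū_g/(k−1)) · k/(k−2)),

defined for k ≥ 3 genes and ≥ 2 samples per group. Negative moment
estimates are truncated at zero and the truncation is flagged in the
result. The stability value combines bias and noise per group,

    SV_i = (1/G) Σ_g sqrt(d_ig² + sigma2_ig / n_g),

reducing to `sqrt(sigma2_i)` for a single group (no inter-group term
exists). This reproduces the intent of the published model-based approach
— an ANOVA-style intra/inter-group decomposition — but applies no
shrinkage to the inter-group differences; the result carries a note to
that effect. An ungrouped mode is provided for sample series where the
grouping is not meaningful.

## BestKeeper-style screening and comparative ΔCt

Descriptive screening works on raw Ct: per-gene mean, min, max, SD and CV
(% of mean Ct), with SD < 1 cycle the conventional stability flag. The
default dispersion is the sample SD; the original tool's mean absolute
deviation is available as `sd_mode="mean_abs_dev"` since published outputs
often use it. When no gene passes the threshold the result carries an
"unsuitable" advisory — the method cannot discriminate candidates on that
design — but the scores are still reported and still contribute to the
comprehensive ranking unless explicitly dropped. The optional BestKeeper
index is the per-sample geometric mean Ct of the chosen panel, with
per-gene Pearson correlations against it (undefined correlations for
zero-variance inputs are reported as NaN, not guessed).

The comparative ΔCt method scores gene i by the mean over partners i′ of
`SD(Ct_i − Ct_i′)`. On perfect-efficiency quantities `log2 Q = Ctmin − Ct`,
so these scores equal geNorm's M exactly; the package keeps both because
they consume different inputs (raw Ct vs quantities) and the identity is a
useful cross-check, enforced by tests at 1e−12.

## Comprehensive ranking

Per-method scores become average (tie-mid) ranks; the comprehensive score
is the geometric mean of a gene's ranks over the included methods, sorted
ascending with ties broken by gene id. Aggregating a single method is the
identity, and improving a gene's rank in one method can never worsen its
geometric mean.

## Candidate screening

The funnel is: per-dataset non-DE gene sets → intersection → removal of
genes with any zero abundance in any dataset → top-N by abundance in a
named reference sample. Because upstream differential-expression pipelines
vary, externally derived non-DE lists are accepted verbatim; the built-in
criterion (max pairwise |log2 FC| of condition means ≤ 1 with pseudocount
1, across-sample CV ≤ 0.5) exists for self-contained use and for the
synthetic datasets. Funnel monotonicity (each stage no larger than the
previous) is asserted on every run.

## 2^−ΔΔCt validation

Fold changes use the classic efficiency-uncorrected form with base 2;
multiple reference genes are combined by the arithmetic mean of their Ct
(equivalently the geometric mean of their quantities). An
efficiency-corrected variant (per-gene bases `1 + E`) is available by
passing an efficiency map. Replicates are averaged on the Ct scale before
ΔCt; since the mean per-replicate ΔCt equals the difference of means, the
point estimates are identical either way and the per-replicate SD is
reported alongside for error bars. Concordance against expression-matrix
fold changes is the mean |log2 fold_qPCR − log2 fold_expr| over targets
and non-calibrator conditions; candidate references are ranked by this
distance ascending.

## Synthetic data: what it emulates and what it does not

The Ct generator draws

    ct_ij = mu_i + s_j + delta_{i,g(j)} + N(0, sigma_i²)

with per-gene baselines `mu_i ~ U(18, 30)` cycles (typical of moderately
to highly expressed transcripts), shared per-sample loading shifts
`s_j ~ N(0, 0.2²)` cycles (cDNA input differences), per-gene×group effects
`delta` (the instability stability methods must detect) and per-gene noise.
A gene's true instability is `sqrt(mean_g delta_ig² + sigma_i²)`, which the
truth record exposes for recovery tests. Scenario presets mirror the three
common designs of a fish reference-gene study: 10 tissues × 3 replicates,
10 developmental stages × 3, and a 2-arm treatment × 3, each with a
12-gene panel. The "graded" scenario spaces noise SDs 0.05–0.6 cycles and
effect scales 0–0.5 cycles across the panel; "planted_winner" gives one
gene sigma = 0.05 among eleven genes with sigma ≥ 0.3.

Because noise is Gaussian on the Ct scale, the geNorm/NormFinder model
assumptions hold *exactly* in simulation. Passing recovery tests therefore
demonstrates correctness of the estimators, not robustness to what real
data add: amplification inhibition, heavy-tailed outliers, missing wells,
plate/run batch effects and efficiency drift are all outside the
generator's scope. The dilution generator likewise produces ideal log-linear
series plus Gaussian noise. Expression matrices are log-normal with planted
stable genes (no condition effect, small noise) and unstable genes given
±1.5–3 log2 condition effects; real RNA-seq count noise, length biases and
dispersion structure are not modeled.

## Numerical conventions and degenerate inputs

* Sample SDs use the n−1 denominator everywhere.
* Log base 2 for all ratios.
* All matrices are genes-in-rows × samples-in-columns.
* Exact ties (identical scores) break lexicographically by gene id, and
  tie-broken orders are recorded in the output.
* The per-gene quantity maximum is forced to exactly 1 after
  exponentiation (floating point can leave it one ulp off).
* Degenerate inputs fail loudly: < 2 genes for pairwise statistics, < 3
  genes for stepwise geNorm and for the NormFinder correction factor
  k/(k−2), single-sample groups, non-positive quantities, non-finite Ct.
* File round-trips are bit-exact (values written with full `repr`
  precision).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use panels of 3–12 genes with
6–60 samples for exact and oracle checks, 100 seeded replicates for
detection-rate measurements, 200 replicates for noisy efficiency recovery,
50 seeds for rank-recovery correlations, n = 200 samples/group for the
variance-consistency check, and a 2000-sample equal-noise panel for the
V-curve decision rule (where the expected curve `V_n ≈ 0.9/sqrt(n(n+1))`
crosses the 0.15 cutoff between n = 5 and n = 6 by construction). The
whole suite runs in a few seconds.

## Known limitations

* The NormFinder-style estimator omits the original's Bayesian shrinkage
  of inter-group differences; rankings can differ from the published tool
  on small groups with weak signal.
* BestKeeper's regression diagnostics and p-value tables are not
  implemented, only SD/CV screening and the index correlation.
* The built-in non-DE criterion is deliberately simple; it is not a
  substitute for a differential-expression analysis when one is available.
* No instrument-native file parsing, melting-curve analysis or Cq
  re-calling; inputs are plain CSV/TSV tables.
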