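# Methods

## Quality control

The QC stage runs in a fixed order: low-count probe filter → global
outlier probe filter → Grubbs probe filter → ROI spike-in filter →
probe→target collapse → LOQ target filter. The order is recorded in the
`QcReport` and permuting probe rows never changes the excluded sets.

**Low-count filter.** A probe is excluded when its count is ≤ 5
(`low_count_threshold`) in strictly more than 2 ROIs
(`low_count_max_rois`). The rule can also be read as "keep only probes
exceeding the threshold in more than 2 ROIs"; that reading is available
via `low_count_alternative_reading`. Negative probes are exempt by
default: they measure background, and removing the low ones would bias
the LOQ upward (`filter_negative_probes_low_count` disables the
exemption).

**Global outlier filter.** A probe is excluded when the ratio of its
geometric mean over all ROIs to the geometric mean of all of its
target's counts (over probes and ROIs) is strictly below 0.1.

**Grubbs filter.** Within each (target, ROI) with ≥ 3 probes, the single
most extreme probe is flagged when `G = max|x_i − mean| / sd` exceeds the
two-sided critical value at α = 0.05,
`G_crit = ((n−1)/√n)·√(t² / (n−2+t²))` with `t` the upper `α/(2n)`
quantile of Student's t on `n−2` df. One pass only — no iterative
removal; `sd = 0` flags nothing. A probe is excluded when flagged in
strictly more than 20 % of ROIs. α and sidedness are conventions of this
implementation (the standard references leave both open for this use);
the test is applied to raw counts.

**ROI spike-in filter.** ROIs whose negative-probe geometric mean falls
strictly below `roi_spikein_min_geomean` (default 10) are dropped.

**LOQ.** Per ROI, `LOQ = geomean · GSD^k` with `GSD = exp(sd(ln counts))`
(sample sd) and `k = 2` — the geometric reading of "two standard
deviations above the geometric mean", which is the standard GeoMx
convention. The arithmetic variant `geomean + k·sd(counts)` is available
via `loq_arithmetic`. Targets with no value above any ROI's LOQ are
dropped.

**Zeros.** Raw zeros are lifted to 1 before any log-space operation, so
the log₂ transform downstream needs no pseudocount.

## Normalization

- **Q3**: each ROI divided by its 75th percentile (linear interpolation
  between order statistics) and rescaled by the geometric mean of all
  Q3s. A within-ROI linear map.
- **CPM**: each ROI divided by its column total × 10 000. Linear.
- **Median-of-ratios (mor)**: values rounded to integers; size factor per
  ROI = median over zero-free targets of value / per-target geometric
  mean. The variance-stabilizing transform that usually follows this
  size-factor step elsewhere is deliberately not reproduced — its
  dispersion-trend machinery is out of proportion to its role here — so
  downstream values are log₂ of size-factor-scaled counts, and every
  report that touches the method states this substitution.
- **Gamma-fit correction**: per ROI a two-parameter gamma is fitted by
  maximum likelihood (location fixed at 0); the reference distribution is
  the arithmetic mean of fitted shapes and rates across ROIs (a pooled
  fit is available via `pooled_reference`); each value maps through
  `Qref(F_roi(x))`. Strictly increasing within each ROI, hence
  rank-preserving.
- **Quantile**: classic rank-average normalization. The reference is the
  mean of sorted columns; ties within a column receive the mean of the
  reference values at the tied ranks (the widely used convention). On
  tie-free columns every column's multiset of output values is exactly
  identical; tie-averaging perturbs the multiset at tied entries only.

Log₂ is applied to all methods; values below 1 are a domain error unless
explicitly floored (the pipeline floors with a warning count, since CPM
routinely produces sub-unit values).

## Benchmarking

Three technical criteria per method, computed on the log₂ matrix:
pairwise two-sample KS statistics between ROI columns (mean D, fraction
of pairs with p < 0.05 — both per-pair and per-ROI summaries are
emitted); the OLS fit of the MA plot, `M` being the per-gene median log₂
fold change between groups and `A = log₂` of the gene's pooled mean
natural-scale expression (slope, R², p); and Spearman's ρ between
per-gene LFC and the sum of group-median S/N — S/N always computed from
the *raw collapsed* matrix, since the statistic diagnoses residual
dependence of each method's output on the raw noise structure. The
biological criterion correlates the deduplicated (strict upper triangle)
marker-gene Spearman correlation vectors of the test matrix and a
reference matrix. A PCA diagnostic reports |Pearson r| between the first
two PC scores (ROIs as observations, centered targets) and per-ROI
median S/N. The composite ranking is the mean of per-criterion ranks —
an artifact convention for a qualitative ordering.

## Differential expression

`lfc = log2(median_A / median_B)` on natural-scale values (log₂ input is
de-logged first). The Wilcoxon rank-sum test is exact when both groups
have ≤ 10 ROIs and the target is tie-free, otherwise the tie- and
continuity-corrected normal approximation; fully tied targets get p = 1.
BH step-up over all tested targets. The test is rank-based, so log₂ vs
natural scale is immaterial to p-values.

## Co-expression network

Signed adjacency `a_ij = ((1+r_ij)/2)^β` on gene–gene Pearson
correlation; β chosen as the smallest candidate whose scale-free fit R²
(log₁₀ frequency vs log₁₀ binned connectivity, sign-corrected) reaches
0.8, argmax with a warning otherwise, or pinned via `power_override`.
The classic topological overlap
`TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` is applied to the
signed adjacency. Modules come from average-linkage clustering of
1 − TOM with a simplified tree cut: the dendrogram is cut at a fraction
of its merge-height *range* selected by `deep_split`
(0..4 → 0.99, 0.97, 0.95, 0.92, 0.90); TOM merge heights bunch just
below the maximum, so a fraction of the range — the convention of
standard dendrogram cutting — separates structure where a quantile of
the merge-height distribution does not. Clusters under `min_module_size`
(30) become grey; modules whose eigengenes correlate above 0.75 are
merged greedily; color labels follow decreasing size (turquoise, blue,
brown, …). The hybrid dynamic tree cut is intentionally not reproduced,
so module counts on real data will differ from the reference R
implementation; planted block structure is recovered exactly.

Eigengenes are the first right-singular vector of the standardized
module block (unit norm, zero mean), sign-oriented so correlation with
the module's average standardized profile is positive — making runs
bit-reproducible. Module–trait and gene–trait associations use Pearson r
with the Student-t p-value `t = r√(n−2)/√(1−r²)` on `n−2` df. Gene-set
over-representation per module is a plain hypergeometric overlap test —
labeled as such, not a pathway-analysis product.

## Synthetic data

The generator emulates a two-condition GeoMx cancer-transcriptome-style
run. For target probe `p` of gene `g` in ROI `r` of group `k`:

    count ~ NegBin(mean = s_r · e_p · μ_g · 2^(δ_g·x_k) · m_gr + b_r, θ)

and negative probes draw `NegBin(b_r, θ)` (gamma–Poisson mixture,
variance `m + m²/θ`). Counts are floored at 1. Group structure enters
through the background only: `b_r` is mean-preserving log-normal around
the group's background mean (spread `background_log_sd`, default 0.5);
capture efficiency `s_r` and probe
efficiency `e_p` are log-normal spreads with no group dependence. That
alone reproduces the artifact: after Q3, the high-background group's
compressed dynamic range tilts the MA plot and couples LFC to S/N.

Defaults define the study conditions: 1500 targets, 3–5 probes per
target, 88 negative probes, 20 ROIs per group, background means
(30, 10), 50 sign-balanced DE targets at |log₂FC| = 1, a 50-gene module
scaled by `1 + trait/λ` with a Poisson(λ = 15) per-ROI trait (T-cell
count). Free parameters chosen once for realism: baseline expression
log-normal with median 100 and log-sd 1.0 (counts spanning roughly
background to several thousand, as a mid-size curated panel does),
ROI efficiency log-sd 0.3, probe efficiency log-sd 0.25, NB dispersion
θ = 8 (moderate overdispersion). The noise law is a modeling
convenience, not a claim about the instrument. Not emulated: spatial
coordinates, segment-level cell composition, slide/batch replicate
structure, probe cross-hybridization — so passing tests demonstrate the
pipeline's behavior under the planted artifact, not performance on any
real tissue.

A second generator, `simulate_module_matrix`, emits a log₂-scale matrix
with `k` planted single-factor modules (within-module correlation 0.8),
independent noise genes, and planted per-gene S/N in which noise genes
sit lowest — the configuration under which the grey module is expected
to carry the lowest S/N.

## Evaluation harness

`dspnorm.evaluation` runs the headline experiments (used by both the
test suite and `scripts/acceptance.py`): a 20-seed bias sweep at the
default study conditions with 4 probes per target; DGE null calibration
(equal backgrounds, nothing planted, 20 seeds) and planted-DE
sensitivity (5 seeds); module recovery on the 300-gene block matrix with
the network power pinned at 16, the workflow's reference power for
quantile-normalized data; gamma MLE recovery at n = 2000. One harness
choice deserves note: the ROI spike-in floor is set to 5 rather than 10
in these experiments. The low-background group is simulated at a mean
background of 10 — exactly the default floor — so a binding floor would
discard most of that group and, with it, the 20-ROIs-per-group design;
at 5 the filter stays operational (genuinely background-starved ROIs are
still dropped, typically 2–6 of 40) while the design survives. Problem
sizes throughout (1500 × 40 pipelines, 20-seed sweeps) keep any single
experiment under a minute on one CPU.

## Known limitations

- The mor method reports log₂ scaled counts, not variance-stabilized
  values; its KS and MA criteria are therefore not directly comparable
  to a VST-based workflow.
- The simplified tree cut has no within-cluster re-splitting; deeply
  nested module structure is returned as one module.
- The scale-free power selection is noisy on small gene sets (a few
  hundred genes); pin `power_override` for toy networks.
- The exact gamma "correction" mapping of the original workflow is not
  published; only rank preservation and distribution alignment are
  inferable, which the CDF-mapping construction here satisfies.
- Sequencing-read-level QC on external datasets is reduced to a generic
  threshold filter on an optional reads-per-ROI column.
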