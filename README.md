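# dspnorm

QC, normalization benchmarking, differential expression and co-expression
network analysis for NanoString GeoMx Digital Spatial Profiler (DSP)
probe-count data — together with a synthetic-data generator that plants
the technical artifact the toolkit is built to expose: a **group-differential
signal-to-noise ratio** that biases Q3-normalized differential expression
and is removed by quantile normalization.

## The problem

GeoMx DSP measures each target gene with 3–5 hybridization probes plus a
panel of negative-control (ERCC spike-in) probes that estimate background.
Per region of interest (ROI) `r`, the background defines a limit of
quantification

    LOQ_r = geomean(negative counts in r) · GSD_r^2,

where GSD is the geometric standard deviation, and a target's
signal-to-noise ratio is `S/N(g, r) = value(g, r) / LOQ_r` with
`value(g, r)` the geometric mean of the target's probes. When study groups
differ systematically in background and signal — as happens between tissue
conditions — the standard third-quartile (Q3) scaling leaves every ROI's
*distribution shape* untouched, so the group with the compressed dynamic
range ends up with inflated low-end values. The result is a tilted MA plot
and differential-expression calls that track S/N instead of biology:
Spearman's ρ between the per-gene log₂ fold change
`lfc(A_c, B_c) = log2(A_c / B_c)` (group median counts) and the summed
group-median S/N becomes strongly negative. Rank-based normalization
(quantile, gamma-fit correction) forces all ROIs onto one distribution and
removes the artifact.

`dspnorm` implements the full workflow:

- **qc** — probe filters (low-count, global outlier, Grubbs), ROI spike-in
  filter, probe→target collapse by geometric mean, LOQ, S/N statistics;
- **normalization** — Q3, modified CPM, median-of-ratios size factors,
  gamma-fit correction, quantile normalization, and the log₂ rule;
- **benchmark** — pairwise Kolmogorov–Smirnov distribution similarity,
  MA-plot OLS deviation from `M = 0`, S/N–LFC Spearman association,
  marker-gene correlation agreement against a reference matrix, and a
  PCA-vs-S/N diagnostic;
- **differential** — per-target Wilcoxon rank-sum with Benjamini–Hochberg
  correction and median-based LFC;
- **network** — signed weighted co-expression analysis: adjacency
  `a_ij = ((1 + cor_ij)/2)^β`, topological overlap, average-linkage
  clustering with a simplified tree cut, module eigengenes, membership,
  and module–trait Pearson correlation with Student-t p-values;
- **simulate** — negative-binomial probe-count generator with per-ROI
  background and capture efficiency, planted DE targets and a planted
  trait-correlated module, emitting the same tabular formats the readers
  consume.

## Worked example

```python
from dspnorm import SimulationConfig, simulate_dataset, run_qc, QcParams, normalize
from dspnorm.differential import wilcoxon_dge
from dspnorm.benchmark import run_benchmark

config = SimulationConfig(seed=1)   # 1500 targets, 20 ROIs/group, background (30, 10)
table, annotations, truth = simulate_dataset(config)

collapsed, noise, report = run_qc(table, QcParams(roi_spikein_min_geomean=5.0),
                                  annotations=annotations)
groups = annotations.groups(collapsed.roi_ids)
matrices = {m: normalize(collapsed, m, log2=True).matrix for m in ("q3", "quantile")}
reports, ranking = run_benchmark(matrices, groups, noise, collapsed)
print(ranking[["ks_mean_d", "ma_r2", "sn_lfc_rho", "pc1_snr_abs_r"]].round(3))

dge = wilcoxon_dge(matrices["quantile"], groups)
```

This prints (QC keeps 1491 targets and 38 of 40 ROIs; per-ROI median S/N
is 2.2 in the high-background group vs 4.0 in the other):

```
          ks_mean_d  ma_r2  sn_lfc_rho  pc1_snr_abs_r
method
quantile      0.001  0.003      -0.073          0.721
q3            0.074  0.431      -0.791          0.901
```

Under Q3 the per-gene fold changes are almost a function of S/N
(ρ = −0.79) and the MA plot is strongly tilted (R² = 0.43); quantile
normalization removes both. The Wilcoxon+BH test on the
quantile-normalized matrix recovers 49 of the 50 planted two-fold DE
targets at padj < 0.05 with 51 calls in total.

The same workflow is available from the shell:

```sh
geomx simulate --out-dir sim --seed 1
geomx qc --counts sim/counts.tsv --annotations sim/annotations.tsv --out-dir qc
geomx normalize --matrix qc/collapsed.csv --method quantile --out norm_quantile.csv
geomx dge --matrix norm_quantile.csv --annotations sim/annotations.tsv --out dge.csv
geomx run --config pipeline.yaml        # end-to-end with a manifest
```

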