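"""Benchmarking framework for normalization methods.

A normalization is judged by three technical criteria and one biological
criterion:

(i)   similarity of per-ROI value distributions (pairwise two-sample
      Kolmogorov-Smirnov tests);
(ii)  deviation of the MA plot from M = 0 (ordinary least-squares fit of
      the per-gene median log2 fold change M on the per-gene log2 mean
      expression A);
(iii) noise interference (Spearman's rho between each gene's log2 fold
      change and the sum of its group-median signal-to-noise ratios);
(iv)  biological agreement (Spearman's rho between the deduplicated
      marker-gene correlation structure of the test matrix and of a bulk
      RNA-seq reference).

A PCA diagnostic quantifies how strongly the leading principal components
of the ROI profiles track per-ROI median S/N — the signature of the
technical bias surviving normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import median_lfc
from .io_tabular import MarkerGeneSet
from .qc import RoiNoiseStats, TargetMatrix, compute_snr


@dataclass
class BenchmarkReport:
    """All criteria for one normalization method."""

    method: str
    ks_summary: dict = field(default_factory=dict)
    ma_fit: dict = field(default_factory=dict)
    sn_lfc: dict = field(default_factory=dict)
    bio_agreement: dict | None = None
    pca_snr: dict | None = None

    def to_row(self) -> dict:
        row = {"method": self.method}
        row["ks_mean_d"] = self.ks_summary.get("mean_d")
        row["ks_frac_significant"] = self.ks_summary.get("frac_significant")
        row["ma_slope"] = self.ma_fit.get("slope")
        row["ma_r2"] = self.ma_fit.get("r2")
        row["sn_lfc_rho"] = self.sn_lfc.get("rho")
        row["sn_lfc_abs_rho"] = abs(self.sn_lfc.get("rho", np.nan))
        if self.bio_agreement is not None:
            row["bio_agreement_rho"] = self.bio_agreement.get("rho")
        if self.pca_snr is not None:
            row["pc1_snr_abs_r"] = self.pca_snr.get("pc1_abs_r")
        return row


def ks_matrix(matrix: TargetMatrix, alpha: float = 0.05) -> dict:
    """All pairwise two-sample KS statistics between ROI columns.

    Returns the symmetric D matrix (zero diagonal), the matching
    asymptotic p-value matrix, the mean off-diagonal D and the fraction of
    pairs with p < ``alpha``; plus per-ROI mean D as a per-sample summary.
    """
    vals = matrix.values
    rois = list(vals.columns)
    if len(rois) < 2:
        raise ValueError("ks_matrix needs >= 2 ROIs")
    n = len(rois)
    d = np.zeros((n, n))
    p = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        res = stats.ks_2samp(vals.iloc[:, i], vals.iloc[:, j], method="asymp")
        d[i, j] = d[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    iu = np.triu_indices(n, k=1)
    return {
        "d_matrix": pd.DataFrame(d, index=rois, columns=rois),
        "p_matrix": pd.DataFrame(p, index=rois, columns=rois),
        "mean_d": float(d[iu].mean()),
        "max_d": float(d[iu].max()),
        "frac_significant": float((p[iu] < alpha).mean()),
        "per_roi_mean_d": pd.Series(d.sum(axis=1) / (n - 1), index=rois),
    }


def ma_deviation(matrix: TargetMatrix, groups: pd.Series) -> dict:
    """OLS fit of the MA plot: M = a + b * A.

    M is the per-gene median log2 fold change between the two groups;
    A is log2 of the gene's mean natural-scale expression over all ROIs
    pooled. Under an unbiased normalization the fit is flat (slope and
    R-squared near 0).
    """
    if matrix.shape[0] < 3:
        raise ValueError("ma_deviation needs >= 3 targets")
    m = median_lfc(matrix, groups)
    a = np.log2(matrix.natural_values().mean(axis=1))
    fit = stats.linregress(a.to_numpy(), m.to_numpy())
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "m": m,
        "a": a,
    }


def sn_lfc_association(lfc: pd.Series, snr_sum: pd.Series) -> dict:
    """Spearman's rho between per-target LFC and summed group-median S/N."""
    snr_sum = snr_sum.loc[lfc.index]
    x = snr_sum.to_numpy(dtype=float)
    y = lfc.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": 0.0, "p": 1.0, "degenerate": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "degenerate": False}


def marker_correlation_agreement(
    matrix: TargetMatrix, reference: TargetMatrix, markers: MarkerGeneSet
) -> dict:
    """Agreement of marker-gene correlation structure with a reference.

    Marker genes present in both matrices form a gene x gene Spearman
    correlation matrix in each; the strict upper triangles (deduplicated
    correlation vectors in matching gene order) are compared by Spearman's
    rho. Genes missing from either matrix are dropped and reported.
    """
    genes = markers.all_genes()
    shared = [g for g in genes if g in matrix.values.index and g in reference.values.index]
    dropped = [g for g in genes if g not in shared]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared marker genes, found {len(shared)}")
    iu = np.triu_indices(len(shared), k=1)

    def upper(mat: TargetMatrix) -> np.ndarray:
        sub = mat.values.loc[shared].to_numpy(dtype=float)
        ranks = np.apply_along_axis(stats.rankdata, 1, sub)
        corr = np.corrcoef(ranks)
        return corr[iu]

    v_test, v_ref = upper(matrix), upper(reference)
    rho, p = stats.spearmanr(v_test, v_ref)
    return {
        "rho": float(rho),
        "p": float(p),
        "n_genes": len(shared),
        "dropped_genes": dropped,
        "pairs": pd.DataFrame({"test": v_test, "reference": v_ref}),
    }


def pca_scores(matrix: TargetMatrix, n_components: int = 2, scale: bool = False) -> pd.DataFrame:
    """Principal-component scores of ROIs over centered target features.

    ROIs are observations, targets features; features are centered
    (optionally standardized). Computed by SVD; each component's sign is
    oriented so its largest-magnitude loading is positive, making scores
    deterministic.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs >= 3 ROIs")
    x = matrix.values.to_numpy(dtype=float).T  # ROIs x targets
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores, index=matrix.roi_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


def pca_snr_diagnostic(matrix: TargetMatrix, noise: RoiNoiseStats) -> dict:
    """|Pearson r| between the first two PC scores and per-ROI median S/N."""
    scores = pca_scores(matrix, n_components=2)
    snr = noise.median_snr.loc[matrix.roi_ids].to_numpy(dtype=float)
    out = {"scores": scores}
    for i, pc in enumerate(scores.columns):
        r = np.corrcoef(scores[pc].to_numpy(), snr)[0, 1]
        out[f"pc{i + 1}_abs_r"] = float(abs(r))
    return out


def run_benchmark(
    matrices: dict[str, TargetMatrix],
    groups: pd.Series,
    noise: RoiNoiseStats,
    collapsed: TargetMatrix,
    markers: MarkerGeneSet | None = None,
    reference: TargetMatrix | None = None,
) -> tuple[dict[str, BenchmarkReport], pd.DataFrame]:
    """All criteria for each normalized matrix, plus a mean-rank table.

    ``matrices`` maps method name to its log2-stage matrix; ``collapsed``
    is the raw collapsed matrix from which the (method-independent) S/N
    statistics are computed. The composite ranking averages the
    per-criterion ranks (lower = better on mean KS D, MA R-squared,
    |S/N-LFC rho| and PC1-S/N |r|; bio agreement ranks higher-is-better
    and is included only when a reference is supplied).
    """
    _, _, raw_group_medians = compute_snr(collapsed, noise, groups)
    snr_sum = raw_group_medians["snr_sum"]
    reports: dict[str, BenchmarkReport] = {}
    for method, matrix in matrices.items():
        lfc = median_lfc(matrix, groups)
        rep = BenchmarkReport(
            method=method,
            ks_summary=ks_matrix(matrix),
            ma_fit=ma_deviation(matrix, groups),
            sn_lfc=sn_lfc_association(lfc, snr_sum.loc[matrix.values.index]),
            pca_snr=pca_snr_diagnostic(matrix, noise),
        )
        if markers is not None and reference is not None:
            rep.bio_agreement = marker_correlation_agreement(matrix, reference, markers)
        reports[method] = rep

    table = pd.DataFrame([r.to_row() for r in reports.values()]).set_index("method")
    rank_cols = {}
    for col, ascending in [
        ("ks_mean_d", True),
        ("ma_r2", True),
        ("sn_lfc_abs_rho", True),
        ("pc1_snr_abs_r", True),
        ("bio_agreement_rho", False),
    ]:
        if col in table.columns and table[col].notna().all():
            rank_cols[col + "_rank"] = table[col].rank(ascending=ascending)
    ranks = pd.DataFrame(rank_cols)
    table["mean_rank"] = ranks.mean(axis=1)
    table = table.sort_values("mean_rank")
    return reports, table
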