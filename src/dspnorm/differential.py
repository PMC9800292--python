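"""Differential expression: median-based log2 fold change and a per-target
Wilcoxon rank-sum test with Benjamini-Hochberg correction.

The fold change of gene c between conditions A and B is
lfc(Ac, Bc) = log2(Ac / Bc) where Ac, Bc are the group median counts on
the natural scale (a log2-stage matrix is de-logged first). The rank-sum
test is exact when both groups have <= 10 ROIs and tie-free, and uses the
tie- and continuity-corrected normal approximation otherwise; the test is
rank-based, so its p-values are identical on log2 and natural scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import TargetMatrix


@dataclass
class DgeResult:
    """Per-target differential-expression table.

    ``table`` columns: ``median_a``, ``median_b`` (group medians,
    natural scale), ``lfc`` (log2(median_a / median_b)), ``statistic``,
    ``p``, ``padj`` (BH) and ``significant`` at ``alpha``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    alpha: float

    @property
    def significant_targets(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _two_group_split(matrix: TargetMatrix, groups: pd.Series) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = groups.loc[matrix.roi_ids]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    a_mask = (groups == labels[0]).to_numpy()
    return labels[0], labels[1], a_mask, ~a_mask


def median_lfc(matrix: TargetMatrix, groups: pd.Series) -> pd.Series:
    """Per-target log2 ratio of group median counts.

    Medians are taken on the natural scale (log2-stage input is de-logged
    first); zero or negative medians are a domain error.
    """
    label_a, label_b, a_mask, b_mask = _two_group_split(matrix, groups)
    if a_mask.sum() < 1 or b_mask.sum() < 1:
        raise ValueError("each group needs at least one ROI")
    vals = matrix.natural_values().to_numpy(dtype=float)
    med_a = np.median(vals[:, a_mask], axis=1)
    med_b = np.median(vals[:, b_mask], axis=1)
    if (med_a <= 0).any() or (med_b <= 0).any():
        raise ValueError("median_lfc requires strictly positive group medians")
    return pd.Series(np.log2(med_a / med_b), index=matrix.values.index, name="lfc")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper over statsmodels)."""
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y)) / 2.0, 1.0
    use_exact = (
        len(x) <= exact_max_n
        and len(y) <= exact_max_n
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_dge(
    matrix: TargetMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    exact_max_n: int = 10,
) -> DgeResult:
    """Two-sided rank-sum test per target with BH correction over targets.

    Exact null enumeration is used when both groups have at most
    ``exact_max_n`` ROIs and the target's values are tie-free; otherwise
    the tie-corrected, continuity-corrected normal approximation.
    """
    label_a, label_b, a_mask, b_mask = _two_group_split(matrix, groups)
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs at least two ROIs for the rank-sum test")
    vals = matrix.natural_values().to_numpy(dtype=float)
    stats_p = np.array(
        [_ranksum_p(row[a_mask], row[b_mask], exact_max_n) for row in vals]
    )
    p = stats_p[:, 1]
    padj = benjamini_hochberg(p)
    med_a = np.median(vals[:, a_mask], axis=1)
    med_b = np.median(vals[:, b_mask], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(med_a / med_b)
    table = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "lfc": lfc,
            "statistic": stats_p[:, 0],
            "p": p,
            "padj": padj,
            "significant": padj < alpha,
        },
        index=matrix.values.index,
    )
    return DgeResult(table, label_a, label_b, alpha)
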