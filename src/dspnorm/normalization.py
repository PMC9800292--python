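"""The five normalization methods compared by the benchmark, plus log2.

Methods
-------
``q3``
    Third-quartile scaling per NanoString guidelines: each ROI divided by
    its 75th percentile, rescaled by the geometric mean of all Q3s so the
    output stays on a count-like scale.
``cpm``
    Modified counts-per-N: each ROI divided by its total and multiplied by
    a scaling factor (default 10 000).
``mor``
    Median-of-ratios size factors on rounded counts (the size-factor step
    of DESeq2). The variance-stabilizing transform is deliberately not
    reproduced: downstream the method's values are log2 of size-factor
    scaled counts, and reports state this substitution.
``gamma``
    Rank-preserving gamma-fit correction: a two-parameter gamma is fitted
    per ROI by maximum likelihood and each ROI is mapped through its own
    fitted CDF onto a common reference gamma (mean shape, mean rate).
``quantile``
    Classic quantile normalization: every ROI is forced onto the shared
    distribution of rank-averaged values; ties share the mean reference
    value.

``q3`` and ``cpm`` are within-ROI linear maps; ``gamma`` and ``quantile``
are within-ROI strictly monotone (rank-preserving) maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qc import TargetMatrix

METHODS = ("q3", "cpm", "mor", "gamma", "quantile")


@dataclass
class NormalizationResult:
    """A normalized matrix plus the factors/parameters that produced it."""

    matrix: TargetMatrix
    method: str
    scale_factors: pd.Series | None = None
    params: dict = field(default_factory=dict)
    log2_floor_warnings: int = 0

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values


def _check_positive(matrix: TargetMatrix, method: str) -> np.ndarray:
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError(f"{method} normalization requires strictly positive values")
    return vals


def q3_normalize(matrix: TargetMatrix) -> NormalizationResult:
    """Scale each ROI so its third quartile aligns across ROIs.

    Quartiles use linear interpolation between order statistics. Values
    are divided by the ROI's Q3 and multiplied by the geometric mean of
    all Q3s, preserving all within-ROI ratios exactly.
    """
    vals = _check_positive(matrix, "q3")
    q3 = np.percentile(vals, 75, axis=0, method="linear")
    ref = float(np.exp(np.mean(np.log(q3))))
    out = vals / q3[None, :] * ref
    factors = pd.Series(ref / q3, index=matrix.roi_ids, name="scale_factor")
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(
        TargetMatrix(frame, stage="normalized(q3)"), "q3", factors, {"q3_reference": ref}
    )


def cpm_normalize(matrix: TargetMatrix, scale: float = 10_000.0) -> NormalizationResult:
    """Divide by the ROI count total and multiply by ``scale``."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    vals = _check_positive(matrix, "cpm")
    totals = vals.sum(axis=0)
    out = vals / totals[None, :] * scale
    factors = pd.Series(scale / totals, index=matrix.roi_ids, name="scale_factor")
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(
        TargetMatrix(frame, stage="normalized(cpm)"), "cpm", factors, {"scale": scale}
    )


def mor_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors on an integer count matrix.

    The reference set is every target with no zero across ROIs; for each
    ROI the size factor is the median over reference targets of
    value / per-target geometric mean.
    """
    vals = counts.to_numpy(dtype=float)
    nonzero = (vals > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("median-of-ratios: every target contains a zero; no reference set")
    ref = vals[nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def mor_normalize(matrix: TargetMatrix) -> NormalizationResult:
    """DESeq2-style size-factor scaling of rounded counts.

    Values are rounded to integers first; size factors come from
    :func:`mor_size_factors`; the output stays on the natural scale
    (log2 is applied downstream by :func:`apply_log2` — this package does
    not reproduce the variance-stabilizing transform).
    """
    vals = _check_positive(matrix, "mor")
    rounded = pd.DataFrame(
        np.round(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    sf = mor_size_factors(rounded)
    out = rounded / sf
    return NormalizationResult(
        TargetMatrix(out, stage="normalized(mor)"),
        "mor",
        sf,
        {"vst_substitute": "log2 of size-factor-scaled counts"},
    )


def _fit_gamma_mle(values: np.ndarray, roi: str) -> tuple[float, float]:
    """Two-parameter gamma MLE (location fixed at 0); returns (shape, rate)."""
    try:
        shape, _, scale = stats.gamma.fit(values, floc=0)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise RuntimeError(f"gamma MLE failed to converge for ROI {roi!r}") from exc
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError(f"gamma MLE failed to converge for ROI {roi!r}")
    return float(shape), float(1.0 / scale)


def gamma_fit_normalize(matrix: TargetMatrix, pooled_reference: bool = False) -> NormalizationResult:
    """Map every ROI through its fitted gamma CDF onto a reference gamma.

    Per ROI a gamma(shape, rate) is fitted by maximum likelihood. The
    reference is the arithmetic mean of fitted shapes and rates across
    ROIs (or, with ``pooled_reference``, one fit to all values pooled).
    Each value x becomes Qref(F_roi(x)); the map is strictly increasing
    within a ROI, so ranks are preserved.
    """
    vals = _check_positive(matrix, "gamma")
    fits = {roi: _fit_gamma_mle(vals[:, j], roi) for j, roi in enumerate(matrix.roi_ids)}
    shapes = np.array([fits[r][0] for r in matrix.roi_ids])
    rates = np.array([fits[r][1] for r in matrix.roi_ids])
    if pooled_reference:
        ref_shape, ref_rate = _fit_gamma_mle(vals.ravel(), "<pooled>")
    else:
        ref_shape, ref_rate = float(shapes.mean()), float(rates.mean())
    out = np.empty_like(vals)
    eps = np.finfo(float).tiny
    for j in range(vals.shape[1]):
        u = stats.gamma.cdf(vals[:, j], shapes[j], scale=1.0 / rates[j])
        u = np.clip(u, eps, 1.0 - 1e-16)
        out[:, j] = stats.gamma.ppf(u, ref_shape, scale=1.0 / ref_rate)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    params = {
        "shapes": pd.Series(shapes, index=matrix.roi_ids),
        "rates": pd.Series(rates, index=matrix.roi_ids),
        "reference_shape": ref_shape,
        "reference_rate": ref_rate,
    }
    return NormalizationResult(TargetMatrix(frame, stage="normalized(gamma)"), "gamma", None, params)


def quantile_normalize(matrix: TargetMatrix) -> NormalizationResult:
    """Force every ROI onto the shared rank-averaged distribution.

    The reference distribution is the mean across ROIs of the sorted
    columns; each value is replaced by the reference value at its rank.
    Ties within a ROI receive the mean of the reference values at the tied
    ranks, so after normalization every column's multiset of values is
    identical (up to the tie-averaging).
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 ROIs")
    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    rows = np.arange(n)
    for j in range(vals.shape[1]):
        col_sorted = vals[order[:, j], j]
        assigned = reference.copy()
        # average the reference over runs of tied input values
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[order[:, j], j] = assigned[rows]
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizationResult(
        TargetMatrix(frame, stage="normalized(quantile)"),
        "quantile",
        None,
        {"reference_distribution": pd.Series(reference)},
    )


def apply_log2(result: NormalizationResult, allow_sub_one: bool = False) -> NormalizationResult:
    """Elementwise log2 of a normalized matrix.

    Values below 1 are a domain error (no pseudocount is ever added)
    unless ``allow_sub_one`` floors them at 1 and counts the floored
    cells in ``log2_floor_warnings``.
    """
    vals = result.values.to_numpy(dtype=float)
    below = vals < 1.0
    n_below = int(below.sum())
    if n_below and not allow_sub_one:
        cells = np.argwhere(below)[:5]
        locs = [
            (result.values.index[i], result.values.columns[j]) for i, j in cells
        ]
        raise ValueError(
            f"log2 of values < 1 ({n_below} cells, first offenders {locs}); "
            "set allow_sub_one to floor them at 1"
        )
    vals = np.maximum(vals, 1.0)
    frame = pd.DataFrame(np.log2(vals), index=result.values.index, columns=result.values.columns)
    return NormalizationResult(
        TargetMatrix(frame, stage=f"log2({result.method})"),
        result.method,
        result.scale_factors,
        result.params,
        log2_floor_warnings=n_below,
    )


def normalize(matrix: TargetMatrix, method: str, log2: bool = True, **kwargs) -> NormalizationResult:
    """Dispatch to one of the five methods, optionally log2-transforming.

    All five methods receive log2 here (the original workflow exempted
    only the variance-stabilized variant, which this package replaces by
    log2 of median-of-ratios scaled counts).
    """
    funcs = {
        "q3": q3_normalize,
        "cpm": cpm_normalize,
        "mor": mor_normalize,
        "gamma": gamma_fit_normalize,
        "quantile": quantile_normalize,
    }
    if method not in funcs:
        raise ValueError(f"unknown normalization method {method!r}; expected one of {METHODS}")
    result = funcs[method](matrix, **kwargs)
    if log2:
        result = apply_log2(result, allow_sub_one=True)
    return result
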