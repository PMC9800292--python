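"""Probe-, ROI- and target-level quality control for GeoMx DSP counts.

The fixed filter order is: low-count probe filter -> global-outlier probe
filter -> Grubbs probe filter -> ROI spike-in filter -> collapse probes to
targets (geometric mean) -> limit-of-quantification (LOQ) target filter.
:func:`run_qc` applies the whole sequence and returns the collapsed matrix
with per-ROI noise statistics and a report of everything excluded.

Background noise is estimated from negative-control (ERCC spike-in) probes:
per ROI, the LOQ is the geometric mean of negative-probe counts raised by
two geometric standard deviations, and a target's signal-to-noise ratio
(S/N) in a ROI is its collapsed value divided by that ROI's LOQ. The
group-wise behaviour of S/N is the central bias diagnostic of the
normalization benchmark.

Any raw zero count is lifted to 1 before log-space operations so that
log2 transforms downstream need no pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_tabular import ProbeCountTable, RoiAnnotationTable


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the QC filters.

    low_count_threshold / low_count_max_rois
        A probe is excluded when its count is <= ``low_count_threshold``
        in more than ``low_count_max_rois`` ROIs.
    global_outlier_ratio
        Minimum allowed ratio of a probe's geometric mean (over ROIs) to
        its target's overall geometric mean; probes strictly below are
        excluded.
    grubbs_alpha / grubbs_roi_fraction
        Two-sided Grubbs significance level per (target, ROI), and the
        fraction of ROIs in which a probe must be flagged before it is
        excluded (strictly more than).
    roi_spikein_min_geomean
        ROIs whose negative-probe geometric mean is strictly below this
        value are excluded.
    loq_sd_multiplier
        Number of (geometric) standard deviations above the negative-probe
        geometric mean that defines the LOQ.
    low_count_alternative_reading
        The low-count rule read as "keep only probes exceeding the
        threshold in more than ``low_count_max_rois`` ROIs" instead of the
        default exclusion reading.
    filter_negative_probes_low_count
        Also subject negative probes to the low-count filter (default off:
        they measure background and dropping low ones biases the LOQ up).
    loq_arithmetic
        Compute LOQ as geomean + multiplier * (arithmetic sd of counts)
        instead of the geometric reading geomean * gsd**multiplier.
    """

    low_count_threshold: float = 5
    low_count_max_rois: int = 2
    global_outlier_ratio: float = 0.1
    grubbs_alpha: float = 0.05
    grubbs_roi_fraction: float = 0.2
    roi_spikein_min_geomean: float = 10.0
    loq_sd_multiplier: float = 2.0
    low_count_alternative_reading: bool = False
    filter_negative_probes_low_count: bool = False
    loq_arithmetic: bool = False

    def __post_init__(self) -> None:
        for name in (
            "low_count_threshold",
            "global_outlier_ratio",
            "grubbs_alpha",
            "grubbs_roi_fraction",
            "roi_spikein_min_geomean",
            "loq_sd_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"QcParams.{name} must be > 0")
        for name in ("grubbs_alpha", "grubbs_roi_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"QcParams.{name} must lie in (0, 1)")
        if self.low_count_max_rois < 0:
            raise ValueError("QcParams.low_count_max_rois must be >= 0")


@dataclass
class QcReport:
    """Everything the QC stage excluded, with reasons, plus survivor counts."""

    excluded_probes: list[tuple[str, str]] = field(default_factory=list)
    excluded_rois: list[tuple[str, str]] = field(default_factory=list)
    excluded_targets: list[tuple[str, str]] = field(default_factory=list)
    survivor_counts: dict[str, int] = field(default_factory=dict)
    filter_order: list[str] = field(default_factory=list)

    def add_probes(self, probe_ids, reason: str) -> None:
        existing = {(p, r) for p, r in self.excluded_probes}
        for p in probe_ids:
            if (p, reason) not in existing:
                self.excluded_probes.append((p, reason))

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("probe", p, r) for p, r in self.excluded_probes]
            + [("roi", p, r) for p, r in self.excluded_rois]
            + [("target", p, r) for p, r in self.excluded_targets]
        )
        return pd.DataFrame(rows, columns=["level", "id", "reason"])


@dataclass
class RoiNoiseStats:
    """Per-ROI background noise statistics from negative probes.

    ``data`` is indexed by roi_id with columns ``neg_geomean``, ``neg_gsd``,
    ``loq`` and (after :func:`compute_snr`) ``median_snr``.
    """

    data: pd.DataFrame

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def loq(self) -> pd.Series:
        return self.data["loq"]

    @property
    def median_snr(self) -> pd.Series:
        return self.data["median_snr"]


@dataclass
class TargetMatrix:
    """Target x ROI value matrix with a processing-stage tag.

    Stages: ``collapsed`` (geometric-mean probe collapse, strictly positive
    raw-scale values), ``normalized(<method>)`` and ``log2(<method>)``.
    """

    values: pd.DataFrame
    stage: str = "collapsed"

    def __post_init__(self) -> None:
        if self.stage == "collapsed" and (self.values.to_numpy() <= 0).any():
            raise ValueError("collapsed-stage matrix must be strictly positive")

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_log2(self) -> bool:
        return self.stage.startswith("log2")

    def natural_values(self) -> pd.DataFrame:
        """Values on the natural (count-like) scale, de-logging if needed."""
        return 2.0 ** self.values if self.is_log2() else self.values


def _lift_zeros(values: np.ndarray) -> np.ndarray:
    """Raw zeros lifted to 1 ahead of log-space operations."""
    return np.maximum(values, 1.0)


def geometric_mean(values) -> float:
    """exp of the mean of natural logs; requires a non-empty positive list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean of an empty list is undefined")
    if (arr <= 0).any():
        raise ValueError("geometric_mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def filter_low_count_probes(
    table: ProbeCountTable, params: QcParams = QcParams()
) -> tuple[ProbeCountTable, list[str]]:
    """Drop probes whose counts stay at or below the threshold too often.

    A probe is excluded iff its count is <= ``low_count_threshold`` in
    strictly more than ``low_count_max_rois`` ROIs. Negative probes are
    exempt unless ``filter_negative_probes_low_count`` is set.
    """
    counts = table.counts.to_numpy(dtype=float)
    if params.low_count_alternative_reading:
        n_high = (counts > params.low_count_threshold).sum(axis=1)
        excluded = ~(n_high > params.low_count_max_rois)
    else:
        n_low = (counts <= params.low_count_threshold).sum(axis=1)
        excluded = n_low > params.low_count_max_rois
    if not params.filter_negative_probes_low_count:
        excluded &= (table.probes["probe_class"] == "target").to_numpy()
    excluded_ids = list(table.probes.loc[excluded, "probe_id"])
    return table.subset(~excluded), excluded_ids


def global_outlier_filter(
    table: ProbeCountTable, params: QcParams = QcParams()
) -> tuple[ProbeCountTable, list[str]]:
    """Drop probes whose overall geometric mean is far below their target's.

    The test statistic is geomean(probe over ROIs) / geomean(all counts of
    the probe's target over probes and ROIs); probes strictly below
    ``global_outlier_ratio`` are excluded. Negative probes are exempt.
    Zeros are lifted to 1 for the log-space means.
    """
    counts = _lift_zeros(table.counts.to_numpy(dtype=float))
    logc = np.log(counts)
    probe_geomean = np.exp(logc.mean(axis=1))
    target_log_mean = (
        pd.Series(logc.mean(axis=1), index=table.probes.index)
        .groupby(table.probes["target_id"])
        .transform("mean")
        .to_numpy()
    )
    ratio = probe_geomean / np.exp(target_log_mean)
    excluded = ratio < params.global_outlier_ratio
    excluded &= (table.probes["probe_class"] == "target").to_numpy()
    excluded_ids = list(table.probes.loc[excluded, "probe_id"])
    return table.subset(~excluded), excluded_ids


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_outlier_filter(
    table: ProbeCountTable, params: QcParams = QcParams()
) -> tuple[ProbeCountTable, list[str]]:
    """Drop probes that are repeatedly Grubbs outliers within their target.

    For each (target, ROI) with >= 3 probes, the single most extreme probe
    is flagged when G = max|x_i - mean| / sd exceeds the two-sided critical
    value at ``grubbs_alpha`` (one pass, no iterative removal; sd = 0 flags
    nothing). A probe is excluded iff flagged in strictly more than
    ``grubbs_roi_fraction`` of ROIs. Targets with fewer than 3 probes are
    skipped.
    """
    probes = table.probes
    targets = probes.loc[probes["probe_class"] == "target", "target_id"]
    counts = table.counts.to_numpy(dtype=float)
    n_rois = counts.shape[1]
    flagged = np.zeros(len(probes), dtype=int)

    # group targets by probe count so each group vectorizes as a 3-D stack
    by_size: dict[int, list[np.ndarray]] = {}
    for _, idx in targets.groupby(targets).groups.items():
        rows = np.asarray(idx)
        by_size.setdefault(len(rows), []).append(rows)
    for n_probes, groups in by_size.items():
        if n_probes < 3:
            continue
        rows = np.stack(groups)                      # (n_targets, n_probes)
        x = counts[rows]                             # (n_targets, n_probes, n_rois)
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        crit = grubbs_critical_value(n_probes, params.grubbs_alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.abs(x - mean) / sd                # nan where sd == 0
        gmax = np.nanmax(np.where(np.isnan(g), -np.inf, g), axis=1, keepdims=True)
        is_extreme = (g == gmax) & np.isfinite(g)
        # flag only the single most extreme probe per (target, ROI); on an
        # exact tie for the extreme, flag the first (ties are measure-zero
        # for continuous-ish counts)
        first_extreme = np.cumsum(is_extreme, axis=1) == 1
        hit = is_extreme & first_extreme & (g > crit)
        np.add.at(flagged, rows, hit.sum(axis=2))

    frac = flagged / n_rois
    excluded = frac > params.grubbs_roi_fraction
    excluded &= (probes["probe_class"] == "target").to_numpy()
    excluded_ids = list(probes.loc[excluded, "probe_id"])
    return table.subset(~excluded), excluded_ids


def filter_rois_by_spikein(
    table: ProbeCountTable, params: QcParams = QcParams()
) -> tuple[ProbeCountTable, list[str]]:
    """Drop ROIs whose negative-probe geometric mean is below the floor."""
    neg = table.negative_probes()
    if neg.n_probes == 0:
        raise ValueError("no negative probes present; cannot apply spike-in ROI filter")
    counts = _lift_zeros(neg.counts.to_numpy(dtype=float))
    geomeans = np.exp(np.log(counts).mean(axis=0))
    keep = geomeans >= params.roi_spikein_min_geomean
    excluded = [r for r, k in zip(table.roi_ids, keep) if not k]
    kept_rois = [r for r, k in zip(table.roi_ids, keep) if k]
    return table.subset_rois(kept_rois), excluded


def collapse_targets(table: ProbeCountTable) -> tuple[TargetMatrix, list[str]]:
    """Collapse target probes to a target x ROI matrix of geometric means.

    Negative probes are not collapsed. Returns the matrix and the list of
    targets dropped because no probe survived (always empty here — upstream
    filters drop probes, so a target absent from the table is already gone;
    the list is kept for report symmetry).
    """
    tgt = table.target_probes()
    if tgt.n_probes == 0:
        raise ValueError("no target probes to collapse")
    logc = np.log(_lift_zeros(tgt.counts.to_numpy(dtype=float)))
    frame = pd.DataFrame(logc, index=tgt.probes["target_id"].to_numpy(), columns=tgt.roi_ids)
    collapsed = np.exp(frame.groupby(level=0, sort=False).mean())
    collapsed.index.name = "target_id"
    return TargetMatrix(collapsed, stage="collapsed"), []


def compute_loq(table: ProbeCountTable, params: QcParams = QcParams()) -> RoiNoiseStats:
    """Per-ROI negative-probe geometric mean, geometric SD and LOQ.

    Geometric reading (default): loq = geomean * gsd**multiplier with
    gsd = exp(sample sd of ln counts). Arithmetic variant
    (``loq_arithmetic``): loq = geomean + multiplier * sd(counts).
    """
    neg = table.negative_probes()
    if neg.n_probes < 2:
        raise ValueError("LOQ requires >= 2 negative probes per ROI")
    counts = _lift_zeros(neg.counts.to_numpy(dtype=float))
    logc = np.log(counts)
    geomean = np.exp(logc.mean(axis=0))
    gsd = np.exp(logc.std(axis=0, ddof=1))
    if params.loq_arithmetic:
        loq = geomean + params.loq_sd_multiplier * counts.std(axis=0, ddof=1)
    else:
        loq = geomean * gsd**params.loq_sd_multiplier
    data = pd.DataFrame(
        {"neg_geomean": geomean, "neg_gsd": gsd, "loq": loq},
        index=pd.Index(table.roi_ids, name="roi_id"),
    )
    return RoiNoiseStats(data)


def filter_targets_by_loq(
    matrix: TargetMatrix, noise: RoiNoiseStats
) -> tuple[TargetMatrix, list[str]]:
    """Keep a target iff at least one ROI value strictly exceeds that ROI's LOQ."""
    loq = noise.loq.loc[matrix.roi_ids].to_numpy()
    above = (matrix.values.to_numpy() > loq[None, :]).any(axis=1)
    excluded = [t for t, k in zip(matrix.target_ids, above) if not k]
    kept = matrix.values.loc[above]
    return TargetMatrix(kept.copy(), stage=matrix.stage), excluded


def compute_snr(
    matrix: TargetMatrix,
    noise: RoiNoiseStats,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame | None]:
    """Signal-to-noise ratios: snr(g, r) = value(g, r) / loq(r).

    Returns the full S/N matrix, the per-ROI median over targets, and —
    when a group assignment is given — a per-target frame with one median
    column per group plus their sum (``snr_sum``), the x-axis of the
    S/N-vs-LFC bias diagnostic. The per-ROI medians are also written back
    into ``noise.data['median_snr']``.
    """
    vals = matrix.natural_values()
    loq = noise.loq.loc[matrix.roi_ids]
    snr = vals / loq
    per_roi_median = snr.median(axis=0)
    noise.data.loc[per_roi_median.index, "median_snr"] = per_roi_median
    group_medians = None
    if groups is not None:
        groups = groups.loc[matrix.roi_ids]
        group_medians = snr.T.groupby(groups).median().T
        group_medians["snr_sum"] = group_medians.sum(axis=1)
    return snr, per_roi_median, group_medians


def run_qc(
    table: ProbeCountTable,
    params: QcParams = QcParams(),
    annotations: RoiAnnotationTable | None = None,
    group_column: str = "group",
) -> tuple[TargetMatrix, RoiNoiseStats, QcReport]:
    """Apply the full fixed-order QC sequence.

    Order: low-count -> global outlier -> Grubbs -> ROI spike-in ->
    collapse -> LOQ target filter, then S/N statistics. The order and all
    exclusions are recorded in the returned :class:`QcReport`.
    """
    report = QcReport(
        filter_order=[
            "low_count",
            "global_outlier",
            "grubbs",
            "roi_spikein",
            "collapse",
            "loq_target_filter",
        ]
    )
    table, low = filter_low_count_probes(table, params)
    report.add_probes(low, "low_count")
    table, glob = global_outlier_filter(table, params)
    report.add_probes(glob, "global_outlier")
    table, grb = grubbs_outlier_filter(table, params)
    report.add_probes(grb, "grubbs")
    table, rois = filter_rois_by_spikein(table, params)
    report.excluded_rois = [(r, "low_spikein_geomean") for r in rois]
    matrix, dropped = collapse_targets(table)
    report.excluded_targets += [(t, "no_surviving_probes") for t in dropped]
    noise = compute_loq(table, params)
    matrix, below = filter_targets_by_loq(matrix, noise)
    report.excluded_targets += [(t, "below_loq") for t in below]
    groups = None
    if annotations is not None:
        annotations.check_covers(matrix.roi_ids)
        groups = annotations.data.set_index("roi_id")[group_column]
    compute_snr(matrix, noise, groups)
    report.survivor_counts = {
        "probes": table.n_probes,
        "rois": table.n_rois,
        "targets": matrix.shape[0],
    }
    return matrix, noise, report
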