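import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dspnorm.qc import (
    QcParams,
    collapse_targets,
    compute_loq,
    compute_snr,
    filter_low_count_probes,
    filter_rois_by_spikein,
    filter_targets_by_loq,
    geometric_mean,
    global_outlier_filter,
    grubbs_critical_value,
    grubbs_outlier_filter,
    run_qc,
)

from conftest import make_probe_table, make_annotations


class TestGeometricMean:
    def test_constant_list(self):
        assert geometric_mean([4, 4, 4]) == pytest.approx(4)

    def test_log_symmetric_pair(self):
        assert geometric_mean([1, 100]) == pytest.approx(10)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            geometric_mean([])
        with pytest.raises(ValueError):
            geometric_mean([1, 0, 2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=1, max_size=30))
    def test_matches_log_mean_formula(self, values):
        expected = np.exp(np.mean(np.log(values)))
        assert geometric_mean(values) == pytest.approx(expected, rel=1e-12)


class TestLowCountFilter:
    def test_high_count_probe_kept(self):
        table = make_probe_table(np.full((1, 10), 100.0), ["G1"])
        kept, excluded = filter_low_count_probes(table)
        assert excluded == []

    def test_boundary_exactly_max_rois_kept(self):
        # <=5 in exactly 2 of 5 ROIs: the rule is strictly "more than 2"
        table = make_probe_table([[5, 5, 6, 6, 6]], ["G1"])
        _, excluded = filter_low_count_probes(table)
        assert excluded == []

    def test_enumeration_on_toy_table(self):
        counts = np.array(
            [
                [10, 10, 10, 10, 10],
                [5, 5, 5, 10, 10],   # <=5 in 3 ROIs -> excluded
                [5, 5, 10, 10, 10],  # <=5 in 2 ROIs -> kept
                [6, 6, 6, 6, 6],
            ],
            dtype=float,
        )
        table = make_probe_table(counts, ["G1", "G1", "G2", "G2"])
        params = QcParams()
        kept, excluded = filter_low_count_probes(table, params)
        # independent enumeration of the rule
        expect = [
            pid
            for pid, row in zip(table.probe_ids, counts)
            if (row <= params.low_count_threshold).sum() > params.low_count_max_rois
        ]
        assert excluded == expect == ["p1"]

    def test_negative_probes_exempt_by_default(self):
        table = make_probe_table(
            [[1, 1, 1, 1], [100, 100, 100, 100]], ["-", "G1"], ["negative", "target"]
        )
        _, excluded = filter_low_count_probes(table)
        assert excluded == []
        _, excluded = filter_low_count_probes(
            table, QcParams(filter_negative_probes_low_count=True)
        )
        assert excluded == ["p0"]


class TestGlobalOutlierFilter:
    def test_identical_probes_all_kept(self):
        table = make_probe_table(np.full((3, 4), 50.0), ["G1"] * 3)
        _, excluded = global_outlier_filter(table)
        assert excluded == []

    def test_hand_computed_low_probe_excluded(self):
        # probe p2 at 0.01x its siblings: ratio = (0.01)^(2/3) ~ 0.046 < 0.1
        counts = np.array([[100.0] * 4, [100.0] * 4, [1.0] * 4])
        table = make_probe_table(counts, ["G1"] * 3)
        _, excluded = global_outlier_filter(table)
        assert excluded == ["p2"]
        ratio = 1.0 / geometric_mean([100, 100, 1])
        assert ratio < 0.1

    def test_ratio_exactly_at_threshold_kept(self):
        counts = np.array([[100.0] * 3, [100.0] * 3, [np.sqrt(10)] * 3])
        table = make_probe_table(counts, ["G1"] * 3)
        ratio = np.sqrt(10) / geometric_mean([100, 100, np.sqrt(10)])
        _, excluded = global_outlier_filter(table, QcParams(global_outlier_ratio=ratio))
        assert excluded == []


class TestGrubbsFilter:
    def test_critical_value_formula(self):
        # independent hand computation of the two-sided critical value
        n, alpha = 4, 0.05
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical_value(4, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_identical_counts_no_flags(self):
        table = make_probe_table(np.full((3, 5), 10.0), ["G1"] * 3)
        _, excluded = grubbs_outlier_filter(table)
        assert excluded == []

    def test_extreme_probe_flagged_and_excluded(self):
        # [10, 11, 12, 100]: G = 1.50 > G_crit(4, 0.05) = 1.48 in every ROI
        counts = np.tile([[10.0], [11.0], [12.0], [100.0]], (1, 5))
        table = make_probe_table(counts, ["G1"] * 4)
        x = counts[:, 0]
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        assert g > grubbs_critical_value(4, 0.05)
        _, excluded = grubbs_outlier_filter(table)
        assert excluded == ["p3"]

    def test_flag_fraction_boundary(self):
        # outlier in 3 of 10 ROIs -> 0.3 > 0.2 -> excluded;
        # in 2 of 10 -> 0.2 not > 0.2 -> kept
        base = np.tile([[10.0], [11.0], [12.0], [11.5]], (1, 10))
        for n_outlier_rois, expect in [(3, ["p3"]), (2, [])]:
            counts = base.copy()
            counts[3, :n_outlier_rois] = 100.0
            table = make_probe_table(counts, ["G1"] * 4)
            _, excluded = grubbs_outlier_filter(table)
            assert excluded == expect

    def test_two_probe_targets_skipped(self):
        table = make_probe_table([[1.0, 1.0], [100.0, 100.0]], ["G1", "G1"])
        _, excluded = grubbs_outlier_filter(table)
        assert excluded == []


class TestRoiSpikeinFilter:
    def test_boundary_geomean_10_kept(self):
        table = make_probe_table(
            [[10, 10], [10, 10], [50, 50]], ["-", "-", "G1"],
            ["negative", "negative", "target"],
        )
        _, excluded = filter_rois_by_spikein(table)
        assert excluded == []

    def test_low_background_roi_excluded(self):
        # negatives [1, 2, 4] -> geomean 2 < 10
        table = make_probe_table(
            [[1, 20], [2, 20], [4, 20], [50, 50]],
            ["-", "-", "-", "G1"],
            ["negative"] * 3 + ["target"],
        )
        _, excluded = filter_rois_by_spikein(table)
        assert excluded == ["R0"]
        assert geometric_mean([1, 2, 4]) == pytest.approx(2)

    def test_requires_negative_probes(self):
        table = make_probe_table([[5, 5]], ["G1"])
        with pytest.raises(ValueError, match="negative probes"):
            filter_rois_by_spikein(table)


class TestCollapse:
    def test_single_probe_identity(self):
        table = make_probe_table([[7, 9, 11]], ["G1"])
        matrix, _ = collapse_targets(table)
        assert matrix.values.loc["G1"].to_numpy() == pytest.approx([7, 9, 11], rel=1e-12)

    def test_pair_geomean(self):
        table = make_probe_table([[2, 2], [8, 8]], ["G1", "G1"])
        matrix, _ = collapse_targets(table)
        assert matrix.values.loc["G1"].tolist() == pytest.approx([4, 4])

    def test_matches_per_cell_formula(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 1000, size=(9, 4)).astype(float)
        targets = ["G1"] * 3 + ["G2"] * 3 + ["G3"] * 3
        matrix, _ = collapse_targets(make_probe_table(counts, targets))
        for i, g in enumerate(["G1", "G2", "G3"]):
            expected = np.exp(np.mean(np.log(counts[3 * i: 3 * i + 3]), axis=0))
            assert matrix.values.loc[g].to_numpy() == pytest.approx(expected, rel=1e-12)


class TestLoq:
    def _neg_table(self, neg_counts):
        neg = np.asarray(neg_counts, dtype=float)[:, None]
        counts = np.vstack([neg, [[50.0]]])
        return make_probe_table(
            counts, ["-"] * len(neg) + ["G1"], ["negative"] * len(neg) + ["target"]
        )

    def test_zero_spread(self):
        stats_ = compute_loq(self._neg_table([7, 7, 7]))
        assert stats_.data["neg_gsd"].iloc[0] == pytest.approx(1.0)
        assert stats_.loq.iloc[0] == pytest.approx(7.0)

    def test_hand_computed_decade_spread(self):
        # negatives [1, 10, 100]: geomean 10, gsd 10, loq 10 * 10^2 = 1000
        stats_ = compute_loq(self._neg_table([1, 10, 100]))
        assert stats_.data["neg_geomean"].iloc[0] == pytest.approx(10, rel=1e-9)
        assert stats_.data["neg_gsd"].iloc[0] == pytest.approx(10, rel=1e-9)
        assert stats_.loq.iloc[0] == pytest.approx(1000, rel=1e-9)

    def test_raising_a_high_count_raises_loq(self):
        base = compute_loq(self._neg_table([5, 10, 20])).loq.iloc[0]
        raised = compute_loq(self._neg_table([5, 10, 30])).loq.iloc[0]
        assert raised > base

    def test_single_negative_probe_rejected(self):
        with pytest.raises(ValueError, match="negative probes"):
            compute_loq(self._neg_table([7]))

    def test_arithmetic_variant(self):
        stats_ = compute_loq(self._neg_table([4, 8, 16]), QcParams(loq_arithmetic=True))
        counts = np.array([4.0, 8.0, 16.0])
        expected = geometric_mean(counts) + 2 * counts.std(ddof=1)
        assert stats_.loq.iloc[0] == pytest.approx(expected, rel=1e-12)


class TestLoqTargetFilter:
    def _setup(self, values):
        table = make_probe_table(
            [[10, 10], [10, 10]], ["-", "-"], ["negative", "negative"]
        )
        noise = compute_loq(table)
        from dspnorm.qc import TargetMatrix

        matrix = TargetMatrix(
            pd.DataFrame(values, index=["G1"], columns=["R0", "R1"]), stage="collapsed"
        )
        return matrix, noise

    def test_always_below_loq_excluded(self):
        matrix, noise = self._setup([[5.0, 9.0]])
        kept, excluded = filter_targets_by_loq(matrix, noise)
        assert excluded == ["G1"]

    def test_single_roi_above_loq_kept(self):
        matrix, noise = self._setup([[5.0, 10.5]])
        kept, excluded = filter_targets_by_loq(matrix, noise)
        assert excluded == []


class TestSnr:
    def test_value_equal_to_loq_gives_one(self):
        from dspnorm.qc import RoiNoiseStats, TargetMatrix

        noise = RoiNoiseStats(
            pd.DataFrame({"neg_geomean": [5.0], "neg_gsd": [1.0], "loq": [20.0]},
                         index=pd.Index(["R0"], name="roi_id"))
        )
        matrix = TargetMatrix(pd.DataFrame([[20.0]], index=["G1"], columns=["R0"]))
        snr, per_roi, _ = compute_snr(matrix, noise)
        assert snr.loc["G1", "R0"] == pytest.approx(1.0)

    def test_linear_in_counts_and_matches_division(self):
        from dspnorm.qc import RoiNoiseStats, TargetMatrix

        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 500, size=(20, 4))
        loq = rng.uniform(20, 60, size=4)
        noise = RoiNoiseStats(
            pd.DataFrame({"neg_geomean": loq / 4, "neg_gsd": 2.0, "loq": loq},
                         index=pd.Index([f"R{j}" for j in range(4)], name="roi_id"))
        )
        matrix = TargetMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(20)],
                         columns=[f"R{j}" for j in range(4)])
        )
        snr, per_roi, _ = compute_snr(matrix, noise)
        assert snr.to_numpy() == pytest.approx(vals / loq[None, :], rel=1e-12)
        doubled = TargetMatrix(matrix.values * 2.0, stage="collapsed")
        snr2, _, _ = compute_snr(doubled, noise)
        assert snr2.to_numpy() == pytest.approx(2 * snr.to_numpy(), rel=1e-12)


class TestPipelineProperties:
    def _random_table(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 400, size=(14, 6)).astype(float)
        counts[12:, :] = rng.integers(8, 40, size=(2, 6))
        targets = [f"G{i // 3}" for i in range(12)] + ["-", "-"]
        classes = ["target"] * 12 + ["negative"] * 2
        return make_probe_table(counts, targets, classes)

    @pytest.mark.parametrize("filt", [
        filter_low_count_probes, global_outlier_filter, grubbs_outlier_filter,
    ])
    def test_filters_idempotent(self, filt):
        table = self._random_table(11)
        once, excl1 = filt(table)
        twice, excl2 = filt(once)
        assert excl2 == []
        assert twice.equals(once)

    def test_probe_order_permutation_does_not_change_exclusions(self):
        table = self._random_table(13)
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.n_probes)
        shuffled = make_probe_table(
            table.counts.to_numpy()[perm],
            [table.probes["target_id"].iloc[i] for i in perm],
            [table.probes["probe_class"].iloc[i] for i in perm],
            probe_ids=[table.probes["probe_id"].iloc[i] for i in perm],
        )
        for filt in (filter_low_count_probes, global_outlier_filter, grubbs_outlier_filter):
            _, e1 = filt(table)
            _, e2 = filt(shuffled)
            assert set(e1) == set(e2)

    def test_run_qc_records_filter_order_and_survivors(self):
        table = self._random_table(17)
        ann = make_annotations([f"R{j}" for j in range(6)], ["a"] * 3 + ["b"] * 3)
        matrix, noise, report = run_qc(table, QcParams(roi_spikein_min_geomean=2.0),
                                       annotations=ann)
        assert report.filter_order[0] == "low_count"
        assert report.filter_order[-1] == "loq_target_filter"
        assert report.survivor_counts["targets"] == matrix.shape[0]
        assert "median_snr" in noise.data.columns
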