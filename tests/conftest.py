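import numpy as np
import pandas as pd
import pytest

from dspnorm.io_tabular import NEGATIVE_SENTINEL, ProbeCountTable, RoiAnnotationTable


def make_probe_table(counts, targets, classes=None, roi_ids=None, probe_ids=None):
    """Assemble a ProbeCountTable from a 2-D array and per-probe metadata."""
    counts = np.asarray(counts, dtype=float)
    n_probes, n_rois = counts.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    roi_ids = roi_ids or [f"R{j}" for j in range(n_rois)]
    classes = classes or ["target"] * n_probes
    targets = [NEGATIVE_SENTINEL if c == "negative" else t for t, c in zip(targets, classes)]
    probes = pd.DataFrame(
        {"probe_id": probe_ids, "target_id": targets, "probe_class": classes}
    )
    mat = pd.DataFrame(counts, index=pd.Index(probe_ids, name="probe_id"), columns=roi_ids)
    return ProbeCountTable(probes, mat)


def make_annotations(roi_ids, groups, **traits):
    data = {"roi_id": roi_ids, "group": groups}
    data.update(traits)
    return RoiAnnotationTable(pd.DataFrame(data))


@pytest.fixture
def tiny_table():
    """6 probes (2 targets x 2 probes + 2 negatives) x 3 ROIs."""
    return make_probe_table(
        counts=[
            [100, 200, 150],
            [80, 160, 120],
            [40, 50, 60],
            [30, 45, 55],
            [12, 14, 16],
            [10, 12, 18],
        ],
        targets=["G1", "G1", "G2", "G2", "-", "-"],
        classes=["target"] * 4 + ["negative"] * 2,
    )
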