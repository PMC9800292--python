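"""Tabular input/output for the GeoMx DSP pipeline.

Three table kinds move through the pipeline: probe-level count matrices
(probes x ROIs plus probe metadata), ROI annotation tables (group labels
and numeric traits such as T-cell counts), and GMT marker-gene sets.
Readers validate structure strictly and fail with located errors rather
than coercing malformed input; every writer produces a file its paired
reader parses back to an equal value.

The canonical on-disk dialect is tab-separated text with a fixed header;
comma-separated files are accepted via ``sep=","``. Written files start
with a ``#``-prefixed schema comment which readers skip.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved target_id sentinel carried by negative-control / spike-in probes.
NEGATIVE_SENTINEL = "NegProbe"

PROBE_CLASSES = ("target", "negative")

_META_COLUMNS = ["probe_id", "target_id", "probe_class"]

SCHEMA_VERSION = "1"


class ParseError(ValueError):
    """Structural problem in an input file, with row/column location."""


@dataclass
class ProbeCountTable:
    """Raw probe x ROI counts plus probe metadata.

    Parameters
    ----------
    probes : pandas.DataFrame
        One row per probe with columns ``probe_id`` (unique), ``target_id``
        and ``probe_class`` (``"target"`` or ``"negative"``). Negative
        probes carry the reserved ``target_id`` :data:`NEGATIVE_SENTINEL`.
    counts : pandas.DataFrame
        Rectangular non-negative count matrix indexed by ``probe_id`` with
        one column per ROI, column order preserved from the source file.
    """

    probes: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        validate_probe_table(self.probes, self.counts)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes["probe_id"])

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_rois(self) -> int:
        return self.counts.shape[1]

    def target_probes(self) -> "ProbeCountTable":
        """Sub-table restricted to target-class probes."""
        return self.subset(self.probes["probe_class"] == "target")

    def negative_probes(self) -> "ProbeCountTable":
        """Sub-table restricted to negative-control probes."""
        return self.subset(self.probes["probe_class"] == "negative")

    def subset(self, probe_mask) -> "ProbeCountTable":
        probes = self.probes.loc[np.asarray(probe_mask)]
        counts = self.counts.loc[probes["probe_id"]]
        return ProbeCountTable(probes.copy(), counts.copy())

    def subset_rois(self, roi_ids: list[str]) -> "ProbeCountTable":
        missing = [r for r in roi_ids if r not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown ROI ids: {missing}")
        return ProbeCountTable(self.probes.copy(), self.counts[roi_ids].copy())

    def equals(self, other: "ProbeCountTable") -> bool:
        return (
            self.probes.reset_index(drop=True).equals(other.probes.reset_index(drop=True))
            and self.counts.equals(other.counts)
        )


@dataclass
class RoiAnnotationTable:
    """Per-ROI annotations: sample/patient ids, group label, numeric traits.

    Columns beyond the recognized ones (``roi_id``, ``sample_id``,
    ``patient_id``, ``group``, ``replicate``) are preserved and treated as
    traits (e.g. ``t_cell_count``).
    """

    data: pd.DataFrame

    _RESERVED = ("roi_id", "sample_id", "patient_id", "group", "replicate")

    def __post_init__(self) -> None:
        if "roi_id" not in self.data.columns:
            raise ParseError("annotation table lacks required column 'roi_id'")
        dup = self.data["roi_id"][self.data["roi_id"].duplicated()]
        if len(dup):
            raise ParseError(f"duplicated roi_id values: {sorted(set(dup))}")
        self.data = self.data.reset_index(drop=True)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data["roi_id"])

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self._RESERVED]

    def groups(self, roi_ids: list[str] | None = None) -> pd.Series:
        """Group label per ROI, indexed by roi_id (optionally reordered)."""
        s = self.data.set_index("roi_id")["group"]
        return s.loc[roi_ids] if roi_ids is not None else s

    def trait(self, name: str, roi_ids: list[str] | None = None) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown trait column {name!r}")
        s = self.data.set_index("roi_id")[name]
        return s.loc[roi_ids] if roi_ids is not None else s

    def check_covers(self, roi_ids: list[str]) -> None:
        missing = sorted(set(roi_ids) - set(self.roi_ids))
        if missing:
            raise ParseError(f"annotations missing ROIs: {missing}")

    def equals(self, other: "RoiAnnotationTable") -> bool:
        return self.data.equals(other.data)


@dataclass
class MarkerGeneSet:
    """Named, ordered gene sets (e.g. cell-type marker lists).

    ``warnings_count`` records how many duplicate genes were dropped while
    reading (duplicates within a set are removed, first occurrence kept).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    warnings_count: int = 0

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {name!r}")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def equals(self, other: "MarkerGeneSet") -> bool:
        return self.sets == other.sets


def validate_probe_table(probes: pd.DataFrame, counts: pd.DataFrame) -> None:
    for col in _META_COLUMNS:
        if col not in probes.columns:
            raise ParseError(f"probe table lacks required column {col!r}")
    dup = probes["probe_id"][probes["probe_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicated probe_id values: {sorted(set(dup))}")
    bad_class = probes.loc[~probes["probe_class"].isin(PROBE_CLASSES), "probe_id"]
    if len(bad_class):
        raise ParseError(
            f"invalid probe_class for probes {list(bad_class)}; expected one of {PROBE_CLASSES}"
        )
    neg = probes["probe_class"] == "negative"
    wrong_sentinel = probes.loc[neg & (probes["target_id"] != NEGATIVE_SENTINEL), "probe_id"]
    if len(wrong_sentinel):
        raise ParseError(
            f"negative probes must use target_id {NEGATIVE_SENTINEL!r}: {list(wrong_sentinel)}"
        )
    if not probes["probe_id"].tolist() == list(counts.index):
        raise ParseError("counts index does not match probe metadata order")
    if counts.isna().any().any():
        cell = np.argwhere(counts.isna().to_numpy())[0]
        raise ParseError(
            f"missing count at probe {counts.index[cell[0]]!r}, ROI {counts.columns[cell[1]]!r}"
        )
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ParseError("non-numeric values in count matrix")
    if (vals < 0).any():
        cell = np.argwhere(vals < 0)[0]
        raise ParseError(
            f"negative count at probe {counts.index[cell[0]]!r}, ROI {counts.columns[cell[1]]!r}"
        )


def _read_table(path, sep: str) -> pd.DataFrame:
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    return pd.read_csv(io.StringIO("".join(lines)), sep=sep, dtype=str)


def read_probe_counts(path, sep: str = "\t") -> ProbeCountTable:
    """Read a probe-level count matrix.

    The header row names the probe metadata columns (``probe_id``,
    ``target_id``, ``probe_class``) followed by one column per ROI; ROI
    column order is preserved. Numeric parsing is strict: any non-numeric
    count cell raises :class:`ParseError` naming its location.
    """
    raw = _read_table(path, sep)
    for col in _META_COLUMNS:
        if col not in raw.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    roi_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    if not roi_cols:
        raise ParseError(f"{path}: no ROI count columns found")
    probes = raw[_META_COLUMNS].copy()
    counts = raw[roi_cols].copy()
    for col in roi_cols:
        converted = pd.to_numeric(counts[col], errors="coerce")
        bad = converted.isna() & counts[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric count {counts.at[row, col]!r} "
                f"for probe {probes.at[row, 'probe_id']!r}, ROI column {col!r}"
            )
        counts[col] = converted
    counts.index = pd.Index(probes["probe_id"], name="probe_id")
    return ProbeCountTable(probes, counts)


def write_probe_counts(table: ProbeCountTable, path, sep: str = "\t") -> None:
    out = table.probes.copy()
    counts = table.counts.reset_index(drop=True)
    for col in table.roi_ids:
        out[col] = counts[col].to_numpy()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# dspnorm probe_counts schema v{SCHEMA_VERSION}\n")
        out.to_csv(fh, sep=sep, index=False)


def read_annotations(path, sep: str = "\t") -> RoiAnnotationTable:
    """Read a ROI annotation table; unknown extra columns become traits."""
    raw = _read_table(path, sep)
    if "roi_id" not in raw.columns:
        raise ParseError(f"{path}: missing required column 'roi_id'")
    for col in raw.columns:
        if col in ("roi_id", "sample_id", "patient_id", "group"):
            continue
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.notna().all():
            raw[col] = converted
    return RoiAnnotationTable(raw)


def write_annotations(table: RoiAnnotationTable, path, sep: str = "\t") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# dspnorm annotations schema v{SCHEMA_VERSION}\n")
        table.data.to_csv(fh, sep=sep, index=False)


def read_gmt(path) -> MarkerGeneSet:
    """Read gene sets in the standard GMT dialect.

    Each line is ``set_name <TAB> description <TAB> gene1 <TAB> gene2 ...``.
    Duplicate genes within a set are dropped (first kept) and counted in
    ``warnings_count``; a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_dropped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    n_dropped += 1
                else:
                    seen.add(g)
                    deduped.append(g)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = deduped
            descriptions[name] = desc
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} duplicate gene(s) within sets")
    return MarkerGeneSet(sets, descriptions, warnings_count=n_dropped)


def write_gmt(markers: MarkerGeneSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in markers.sets.items():
            desc = markers.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_matrix_csv(path, sep: str = ",") -> pd.DataFrame:
    """Read a target x ROI value matrix written by :func:`write_matrix_csv`."""
    raw = _read_table(path, sep)
    first = raw.columns[0]
    mat = raw.set_index(first)
    mat.index.name = "target_id"
    for col in mat.columns:
        converted = pd.to_numeric(mat[col], errors="coerce")
        bad = converted.isna() & mat[col].notna()
        if bad.any():
            raise ParseError(f"{path}: non-numeric value in column {col!r}")
        mat[col] = converted
    return mat


def write_matrix_csv(matrix: pd.DataFrame, path, sep: str = ",", schema: str = "matrix") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# dspnorm {schema} schema v{SCHEMA_VERSION}\n")
        matrix.to_csv(fh, sep=sep, index=True, index_label="target_id")
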