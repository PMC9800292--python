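"""End-to-end orchestration: simulate/load -> QC -> normalize -> benchmark
-> differential expression -> network, with a reproducibility manifest.

A run is driven by one :class:`PipelineConfig` (constructible from YAML).
Every stage writes its outputs into the run directory and the manifest
records parameters, the seed and a SHA-256 hash of every file, so an
identical config and seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_tabular as io
from .benchmark import run_benchmark
from .differential import wilcoxon_dge
from .network import NetworkParams, run_network
from .normalization import METHODS, normalize
from .qc import QcParams, TargetMatrix, compute_snr, run_qc
from .simulate import SimulationConfig, simulate_dataset


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One run's worth of configuration.

    Either ``counts_path``/``annotations_path`` point at input files, or
    ``simulation`` holds a :class:`SimulationConfig` and the pipeline
    generates its own input.
    """

    out_dir: str = "geomx_run"
    counts_path: str | None = None
    annotations_path: str | None = None
    simulation: SimulationConfig | None = None
    qc_params: QcParams = field(default_factory=QcParams)
    methods: tuple[str, ...] = METHODS
    group_column: str = "group"
    trait_columns: tuple[str, ...] = ()
    network_params: NetworkParams = field(default_factory=NetworkParams)
    network_method: str = "quantile"
    markers_path: str | None = None
    reference_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one normalization method is required")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; expected subset of {METHODS}")
        if self.simulation is None and self.counts_path is None:
            raise ValueError("either input paths or a simulation config is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim = dict(kwargs["simulation"])
            for key in ("probes_per_target_range", "group_labels", "background_mean_by_group"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "qc_params" in kwargs and kwargs["qc_params"] is not None:
            kwargs["qc_params"] = QcParams(**kwargs["qc_params"])
        if "network_params" in kwargs and kwargs["network_params"] is not None:
            net = dict(kwargs["network_params"])
            if "candidate_powers" in net:
                net["candidate_powers"] = tuple(net["candidate_powers"])
            kwargs["network_params"] = NetworkParams(**net)
        for key in ("methods", "trait_columns"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing outputs and a manifest under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``). Any
    stage error raises :class:`PipelineError` naming the stage; outputs of
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            manifest["stages"][stage].append(p.name)
            manifest["files"][p.name] = _sha256(p)

    # ---- input ----
    stage = "input"
    try:
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            table, annotations, truth = simulate_dataset(sim_cfg)
            counts_path = out / "simulated_counts.tsv"
            ann_path = out / "simulated_annotations.tsv"
            io.write_probe_counts(table, counts_path)
            io.write_annotations(annotations, ann_path)
            truth_path = out / "simulated_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "de_log2fc": truth.de_log2fc,
                        "module_target_ids": truth.module_target_ids,
                        "seed": sim_cfg.seed,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            record(stage, counts_path, ann_path, truth_path)
        else:
            table = io.read_probe_counts(config.counts_path)
            annotations = io.read_annotations(config.annotations_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- qc ----
    stage = "qc"
    try:
        collapsed, noise, report = run_qc(
            table, config.qc_params, annotations, config.group_column
        )
        io.write_matrix_csv(collapsed.values, out / "collapsed.csv", schema="collapsed")
        noise.data.to_csv(out / "roi_noise_stats.csv")
        report.to_frame().to_csv(out / "qc_report.csv", index=False)
        (out / "qc_log.txt").write_text(
            "QC filter order: " + " -> ".join(report.filter_order) + "\n"
            + f"survivors: {report.survivor_counts}\n"
            + f"excluded probes: {len(report.excluded_probes)}, "
            + f"rois: {len(report.excluded_rois)}, targets: {len(report.excluded_targets)}\n"
        )
        record(stage, out / "collapsed.csv", out / "roi_noise_stats.csv",
               out / "qc_report.csv", out / "qc_log.txt")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    groups = annotations.groups(collapsed.roi_ids)

    # ---- normalization ----
    stage = "normalize"
    normalized: dict[str, TargetMatrix] = {}
    try:
        for method in config.methods:
            result = normalize(collapsed, method, log2=True)
            normalized[method] = result.matrix
            path = out / f"norm_{method}.csv"
            io.write_matrix_csv(result.matrix.values, path, schema=f"log2({method})")
            record(stage, path)
            if result.scale_factors is not None:
                sf_path = out / f"norm_{method}_factors.csv"
                result.scale_factors.rename_axis("roi_id").to_csv(sf_path)
                record(stage, sf_path)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- benchmark ----
    stage = "benchmark"
    try:
        markers = io.read_gmt(config.markers_path) if config.markers_path else None
        reference = None
        if config.reference_path:
            reference = TargetMatrix(
                io.read_matrix_csv(config.reference_path), stage="log2(reference)"
            )
        reports, ranking = run_benchmark(
            normalized, groups, noise, collapsed, markers=markers, reference=reference
        )
        ranking.to_csv(out / "benchmark_ranking.csv")
        record(stage, out / "benchmark_ranking.csv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- differential expression ----
    stage = "dge"
    try:
        for method, matrix in normalized.items():
            dge = wilcoxon_dge(matrix, groups)
            path = out / f"dge_{method}.csv"
            dge.table.rename_axis("target_id").to_csv(path)
            record(stage, path)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- network ----
    stage = "network"
    try:
        net_matrix = normalized[config.network_method] if config.network_method in normalized \
            else next(iter(normalized.values()))
        traits = None
        if config.trait_columns:
            traits = annotations.data.set_index("roi_id")[list(config.trait_columns)]
            traits = traits.loc[net_matrix.roi_ids]
        snr, _, _ = compute_snr(collapsed, noise)
        net = run_network(net_matrix, config.network_params, traits=traits, snr=snr)
        net.modules.rename_axis("target_id").to_csv(out / "network_modules.csv")
        net.eigengenes.rename_axis("roi_id").to_csv(out / "network_eigengenes.csv")
        net.fit_table.to_csv(out / "network_fit_table.csv")
        paths = [out / "network_modules.csv", out / "network_eigengenes.csv",
                 out / "network_fit_table.csv"]
        if net.trait_correlation is not None:
            net.trait_correlation.rename_axis("module").to_csv(out / "network_trait_cor.csv")
            paths.append(out / "network_trait_cor.csv")
        if net.module_snr is not None:
            net.module_snr.to_csv(out / "network_module_snr.csv")
            paths.append(out / "network_module_snr.csv")
        record(stage, *paths)
        manifest["network_power"] = net.power
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest["methods"] = list(config.methods)
    manifest["benchmark_ranking"] = ranking.index.tolist()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
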