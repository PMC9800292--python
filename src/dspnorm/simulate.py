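"""Synthetic GeoMx-DSP-like probe-count data with known ground truth.

The generator emulates the structure of a cancer-transcriptome-atlas style
run: ~1800 target genes measured by 3-5 probes each, 88 negative-control
(ERCC spike-in) probes, and two ROI groups (e.g. primary vs recurrent
resections). Its defining feature is a *group-differential signal-to-noise
ratio*: one group can be given a higher expected background count and a
correspondingly lower capture efficiency, which reproduces the technical
bias that skews Q3-normalized differential expression and is removed by
rank-based normalization.

Count model. For target probe p of target g in ROI r of group k:

    count ~ NegBin(mean = s_r * e_p * mu_g * 2^(delta_g * x_k) * m_{g,r} + b_r,
                   dispersion = nb_dispersion)

and for a negative probe, count ~ NegBin(mean = b_r, dispersion). Here
s_r is the ROI capture efficiency (log-normal spread around 1),
e_p the probe efficiency (log-normal), mu_g the baseline expression
(log-normal across targets), delta_g the planted log2 fold change (zero
except for DE targets, sign-balanced), x_k in {0, 1} the group indicator,
b_r the ROI background level (mean-preserving log-normal around the
group's background mean), and
m_{g,r} = 1 + trait_r / trait_poisson_mean a trait-driven multiplier
applied only to the planted module targets (trait_r ~ Poisson, emulating
per-ROI T-cell counts). Counts are floored at 1 so no value is below 1
and downstream log2 transforms need no pseudocount.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tabular import NEGATIVE_SENTINEL, ProbeCountTable, RoiAnnotationTable
from .qc import TargetMatrix


class ConfigurationError(ValueError):
    """An invalid simulation-configuration field, named in the message."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe the study conditions the simulator is meant to
    emulate: 1500 targets with 3-5 probes each, 88 negative probes,
    20 ROIs per group, group background means (30, 10) producing the
    group-differential S/N gap, 50 sign-balanced DE targets at |log2 FC|
    = 1, and a 50-gene module whose expression tracks a Poisson-distributed
    per-ROI trait (T-cell count).
    """

    n_targets: int = 1500
    probes_per_target_range: tuple[int, int] = (3, 5)
    n_negative_probes: int = 88
    n_rois_per_group: int = 20
    group_labels: tuple[str, str] = ("primary", "recurrent")
    baseline_log_expr_mean: float = float(np.log(100.0))
    baseline_log_expr_sd: float = 1.0
    background_mean_by_group: tuple[float, float] = (30.0, 10.0)
    background_log_sd: float = 0.5
    efficiency_log_sd: float = 0.3
    probe_efficiency_log_sd: float = 0.25
    nb_dispersion: float = 8.0
    n_de_targets: int = 50
    de_log2fc: float = 1.0
    n_module_targets: int = 50
    module_trait_name: str = "t_cell_count"
    trait_poisson_mean: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid SimulationConfig.{name}: {why}")

        for name in ("n_targets", "n_negative_probes", "n_rois_per_group",
                     "n_de_targets", "n_module_targets"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        lo, hi = self.probes_per_target_range
        if not (1 <= lo <= hi <= 10):
            raise bad("probes_per_target_range", "must satisfy 1 <= lo <= hi <= 10")
        if any(b <= 0 for b in self.background_mean_by_group):
            raise bad("background_mean_by_group", "background means must be > 0")
        if self.nb_dispersion <= 0:
            raise bad("nb_dispersion", "must be > 0")
        if self.trait_poisson_mean <= 0:
            raise bad("trait_poisson_mean", "must be > 0")
        for name in ("efficiency_log_sd", "probe_efficiency_log_sd",
                     "baseline_log_expr_sd", "background_log_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        if self.n_de_targets + self.n_module_targets > self.n_targets:
            raise bad("n_de_targets", "n_de_targets + n_module_targets exceeds n_targets")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise bad("group_labels", "needs two distinct labels")
        if len(self.background_mean_by_group) != 2:
            raise bad("background_mean_by_group", "needs one mean per group")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset.

    ``de_log2fc`` maps DE target ids to signed planted log2 fold changes
    (group 2 relative to group 1); ``module_target_ids`` lists the
    trait-driven module; ``trait`` holds the integer trait per ROI;
    ``roi_background`` (b_r), ``roi_efficiency`` (s_r) and
    ``probe_efficiency`` (e_p) expose the latent technical factors;
    ``expected_snr`` is the noise-free per-ROI median S/N implied by the
    latent factors, before counts are drawn.
    """

    de_log2fc: dict[str, float]
    module_target_ids: list[str]
    trait: pd.Series
    roi_background: pd.Series
    roi_efficiency: pd.Series
    probe_efficiency: pd.Series
    baseline_expression: pd.Series
    expected_snr: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def de_target_ids(self) -> list[str]:
        return list(self.de_log2fc)


def _nbinom_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via the gamma-Poisson mixture; var = m + m^2/theta."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ProbeCountTable, RoiAnnotationTable, SyntheticTruth]:
    """Draw one synthetic probe-count dataset with annotations and truth.

    Deterministic given ``config.seed``; all counts are integers >= 1.
    """
    rng = np.random.default_rng(config.seed)
    n_g = config.n_targets
    n_r = 2 * config.n_rois_per_group

    target_ids = [f"T{i:05d}" for i in range(n_g)]
    roi_ids = [
        f"ROI_{lab}_{i:03d}"
        for lab in config.group_labels
        for i in range(config.n_rois_per_group)
    ]
    group_idx = np.repeat([0, 1], config.n_rois_per_group)

    # probes per target
    lo, hi = config.probes_per_target_range
    n_probes_per_target = rng.integers(lo, hi + 1, size=n_g)
    probe_target = np.repeat(np.arange(n_g), n_probes_per_target)
    probe_ids = [
        f"{target_ids[t]}_p{j + 1}"
        for t, n in zip(range(n_g), n_probes_per_target)
        for j in range(n)
    ]
    n_target_probes = len(probe_ids)

    # latent expression and technical factors
    mu = np.exp(rng.normal(config.baseline_log_expr_mean, config.baseline_log_expr_sd, n_g))
    e_p = np.exp(rng.normal(0.0, config.probe_efficiency_log_sd, n_target_probes))
    bg_means = np.asarray(config.background_mean_by_group, dtype=float)
    # mean-preserving lognormal ROI background around the group mean
    b_sd = config.background_log_sd
    b_r = bg_means[group_idx] * np.exp(rng.normal(-0.5 * b_sd**2, b_sd, n_r))
    s_r = np.exp(rng.normal(0.0, config.efficiency_log_sd, n_r))

    # planted structure: DE targets (sign-balanced), then module targets
    special = rng.choice(n_g, size=config.n_de_targets + config.n_module_targets, replace=False)
    de_idx = special[: config.n_de_targets]
    module_idx = special[config.n_de_targets:]
    delta = np.zeros(n_g)
    signs = np.where(np.arange(config.n_de_targets) % 2 == 0, 1.0, -1.0)
    delta[de_idx] = signs * config.de_log2fc

    trait = rng.poisson(config.trait_poisson_mean, size=n_r)
    module_mult = np.ones((n_g, n_r))
    module_mult[module_idx, :] = 1.0 + trait[None, :] / config.trait_poisson_mean

    # expected target signal per (gene, ROI) on the count scale
    fold = 2.0 ** (delta[:, None] * group_idx[None, :])
    signal_gr = mu[:, None] * fold * module_mult * s_r[None, :]

    mean_target = signal_gr[probe_target, :] * e_p[:, None] + b_r[None, :]
    counts_target = _nbinom_draw(rng, mean_target, config.nb_dispersion)
    mean_neg = np.broadcast_to(b_r[None, :], (config.n_negative_probes, n_r)).copy()
    counts_neg = _nbinom_draw(rng, mean_neg, config.nb_dispersion)

    neg_ids = [f"NEG_p{j + 1:02d}" for j in range(config.n_negative_probes)]
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids + neg_ids,
            "target_id": [target_ids[t] for t in probe_target] + [NEGATIVE_SENTINEL] * config.n_negative_probes,
            "probe_class": ["target"] * n_target_probes + ["negative"] * config.n_negative_probes,
        }
    )
    counts = pd.DataFrame(
        np.maximum(np.vstack([counts_target, counts_neg]), 1).astype(np.int64),
        index=pd.Index(probes["probe_id"], name="probe_id"),
        columns=roi_ids,
    )
    table = ProbeCountTable(probes, counts)

    annotations = RoiAnnotationTable(
        pd.DataFrame(
            {
                "roi_id": roi_ids,
                "sample_id": [f"S_{lab}_{i:03d}" for lab in config.group_labels
                              for i in range(config.n_rois_per_group)],
                "patient_id": [f"P{i:03d}" for _ in config.group_labels
                               for i in range(config.n_rois_per_group)],
                "group": [config.group_labels[k] for k in group_idx],
                config.module_trait_name: trait,
                "seed": config.seed,
            }
        )
    )

    roi_index = pd.Index(roi_ids, name="roi_id")
    # noise-free S/N implied by the latent factors (LOQ ~ background level)
    expected_snr = pd.Series(
        np.median(signal_gr / b_r[None, :], axis=0), index=roi_index, name="expected_snr"
    )
    truth = SyntheticTruth(
        de_log2fc={target_ids[i]: float(delta[i]) for i in de_idx},
        module_target_ids=[target_ids[i] for i in sorted(module_idx)],
        trait=pd.Series(trait, index=roi_index, name=config.module_trait_name),
        roi_background=pd.Series(b_r, index=roi_index, name="b_r"),
        roi_efficiency=pd.Series(s_r, index=roi_index, name="s_r"),
        probe_efficiency=pd.Series(e_p, index=pd.Index(probe_ids, name="probe_id"), name="e_p"),
        baseline_expression=pd.Series(mu, index=pd.Index(target_ids, name="target_id"), name="mu"),
        expected_snr=expected_snr,
    )
    return table, annotations, truth


def simulate_module_matrix(
    n_modules: int = 3,
    genes_per_module: int = 50,
    n_noise_genes: int = 150,
    n_rois: int = 40,
    within_module_cor: float = 0.8,
    noise_snr: float = 0.5,
    module_snr: float = 10.0,
    seed: int = 0,
) -> tuple[TargetMatrix, pd.Series, pd.Series]:
    """Log2-scale expression matrix with planted co-expression modules.

    Module genes load on one latent factor per module (pairwise correlation
    ``within_module_cor``); noise genes are independent. Returns the
    matrix, the true module label per gene (``"M1"`` ... , ``"noise"``),
    and a planted per-gene median S/N in which noise genes sit lowest —
    the configuration in which the unassigned (grey) module is expected to
    have the lowest S/N.
    """
    if not (0 < within_module_cor < 1):
        raise ConfigurationError("within_module_cor must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    loading = np.sqrt(within_module_cor)
    resid = np.sqrt(1.0 - within_module_cor)
    blocks = []
    labels = []
    for m in range(n_modules):
        factor = rng.normal(size=n_rois)
        eps = rng.normal(size=(genes_per_module, n_rois))
        blocks.append(loading * factor[None, :] + resid * eps)
        labels += [f"M{m + 1}"] * genes_per_module
    blocks.append(rng.normal(size=(n_noise_genes, n_rois)))
    labels += ["noise"] * n_noise_genes
    x = np.vstack(blocks) + 8.0  # arbitrary positive log2 baseline
    gene_ids = [f"G{i:04d}" for i in range(x.shape[0])]
    idx = pd.Index(gene_ids, name="target_id")
    matrix = TargetMatrix(
        pd.DataFrame(x, index=idx, columns=[f"ROI_{j:03d}" for j in range(n_rois)]),
        stage="log2(synthetic)",
    )
    truth = pd.Series(labels, index=idx, name="module")
    snr = pd.Series(
        np.where(np.asarray(labels) == "noise", noise_snr, module_snr)
        * rng.uniform(0.8, 1.25, size=len(labels)),
        index=idx,
        name="median_snr",
    )
    return matrix, truth, snr
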