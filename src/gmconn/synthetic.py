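"""Synthetic infant cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: three groups of 45 infants
(preterm infants scanned twice, PT:ses1 in the preterm period and PT:ses2
near term-equivalent age, plus matched full-term FT neonates), each with a
regional diffusion-metric table and per-subject regional BOLD series.

Structure is planted through a latent-factor block model: ROIs are
partitioned into blocks, and all metrics of the ROIs in a block load on a
shared per-subject factor, which makes fingerprints within a block
correlate across subjects (the MC signal).  BOLD series mix a shared
per-block latent signal with independent noise so that within-block
temporal correlation equals a planted value (the FC signal).  Linear
age effects (PMA at scan, GA at birth) and an additive per-subject global
offset play the role of the confounds the pipeline residualizes.
Longitudinal change between the two preterm sessions is planted as
per-block shifts of the block strengths, shared between the two
modalities (coupled co-evolution) or drawn independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import default_atlas
from .fc import ROITimeSeriesSet
from .mc import GROUPS, METRICS, CohortMetricTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "CohortDataset", "generate_cohort"]

# Baseline regional values and stochastic amplitudes per metric, in each
# metric's natural units (diffusivities in mm^2/s).  Chosen to sit in the
# range reported for neonatal grey matter; the amplitude sets the scale of
# the structured + noise component so unitless metrics stay in [0, 1].
METRIC_BASELINES = {"FA": 0.25, "AD": 1.7e-3, "RD": 1.3e-3, "MD": 1.4e-3, "NDI": 0.25, "ODI": 0.40}
METRIC_AMPLITUDES = {"FA": 0.03, "AD": 1.2e-4, "RD": 1.2e-4, "MD": 1.2e-4, "NDI": 0.03, "ODI": 0.03}

# Age ranges (weeks) per group: PMA at scan and GA at birth, matching the
# cohort the generator emulates.
PMA_RANGES = {"PT:ses1": (28.3, 36.9), "PT:ses2": (38.4, 44.9), "FT": (38.4, 44.9)}
GA_RANGES = {"PT": (25.6, 36.0), "FT": (37.4, 42.3)}
PMA_CENTER = 38.0
GA_CENTER = 32.0


def _default_betas() -> dict[str, tuple[float, float]]:
    """Mild per-week age effects (PMA, GA) per metric, natural units.

    Signs follow the usual perinatal grey-matter trends: anisotropy and
    diffusivities fall with age while neurite density and dispersion rise.
    """
    return {
        "FA": (-0.004, -0.002),
        "AD": (-1.5e-5, -0.7e-5),
        "RD": (-1.0e-5, -0.5e-5),
        "MD": (-1.2e-5, -0.6e-5),
        "NDI": (0.006, 0.003),
        "ODI": (0.004, 0.002),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_subjects: int = 45
    n_rois: int = 75
    n_blocks: int = 5
    #: optional explicit ROI->block maps; default: contiguous equal blocks
    mc_block_map: tuple[int, ...] | None = None
    fc_block_map: tuple[int, ...] | None = None
    #: within-block latent-factor loading of the metric model
    block_correlation: float = 0.6
    #: dimensionality and loading of the fine-scale similarity geometry
    #: (shared across modalities when ``modalities_shared``)
    fine_dim: int = 10
    fine_loading: float = 0.35
    #: per-metric (beta_PMA, beta_GA), units of the metric per week
    confound_betas: dict[str, tuple[float, float]] = field(default_factory=_default_betas)
    #: SD of the additive per-subject global offset (amplitude units)
    global_scale_sd: float = 0.3
    #: SD of fixed per-(ROI, metric) baseline jitter (amplitude units)
    roi_jitter_sd: float = 0.3
    #: residual SD per metric (amplitude units)
    noise_sd: float = 0.5
    ts_length: int = 300
    sampling_interval: float = 0.392
    #: planted within-block temporal correlation of the BOLD series
    fc_block_rho: float = 0.6
    #: magnitude of the per-block strength shift between preterm sessions
    delta_effect: float = 0.3
    #: share block partitions and per-block delta draws across modalities
    modalities_shared: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects per group (correlations undefined)")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must lie in [0, 1)")
        if not (0 <= self.fc_block_rho < 1):
            raise ValueError("fc_block_rho must lie in [0, 1)")
        if self.noise_sd <= 0 or self.global_scale_sd < 0:
            raise ValueError("noise/scale SDs must be positive")
        if self.ts_length <= 100:
            raise ValueError("ts_length must exceed 100")
        for m in METRICS:
            if m not in self.confound_betas:
                raise ValueError(f"confound_betas missing metric {m!r}")

    def resolved_block_map(self, modality: str) -> np.ndarray:
        explicit = self.mc_block_map if modality == "MC" else self.fc_block_map
        if explicit is not None:
            bm = np.asarray(explicit, dtype=int)
            if bm.shape != (self.n_rois,):
                raise ValueError(f"{modality} block map must have {self.n_rois} entries")
            return bm
        # contiguous, nearly equal blocks
        return np.minimum(
            np.arange(self.n_rois) * self.n_blocks // self.n_rois, self.n_blocks - 1
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything planted: block maps, session strengths, covariate draws."""

    mc_blocks: np.ndarray
    fc_blocks: np.ndarray
    mc_loading_by_group: dict[str, np.ndarray]
    fc_rho_by_group: dict[str, np.ndarray]
    block_delta_mc: np.ndarray
    block_delta_fc: np.ndarray
    mc_fine: np.ndarray
    fc_fine: np.ndarray
    covariates: pd.DataFrame
    confound_betas: dict[str, tuple[float, float]]
    seed: int

    def save_json(self, path: str | Path) -> None:
        payload = {
            "mc_blocks": self.mc_blocks.tolist(),
            "fc_blocks": self.fc_blocks.tolist(),
            "mc_loading_by_group": {g: v.tolist() for g, v in self.mc_loading_by_group.items()},
            "fc_rho_by_group": {g: v.tolist() for g, v in self.fc_rho_by_group.items()},
            "block_delta_mc": self.block_delta_mc.tolist(),
            "block_delta_fc": self.block_delta_fc.tolist(),
            "mc_fine": self.mc_fine.tolist(),
            "fc_fine": self.fc_fine.tolist(),
            "covariates": self.covariates.to_dict(orient="list"),
            "confound_betas": {m: list(b) for m, b in self.confound_betas.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass(frozen=True)
class CohortDataset:
    """Generator output: per-group metric tables and time series, plus truth."""

    metrics: dict[str, CohortMetricTable]
    timeseries: dict[str, list[ROITimeSeriesSet]]
    truth: SyntheticTruth


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    """Named, independent RNG substreams; adding draws to one stage never
    perturbs another."""
    names = ("covariates", "blocks", "metrics", "timeseries", "deltas")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate the three groups with planted structure (bit-reproducible).

    The metric model per subject s, ROI r, metric m is::

        x = mu_m + jitter[r, m] + b_PMA * (PMA_s - 38) + b_GA * (GA_s - 32)
            + amp_m * (g_s + lambda_b * f[s, block(r)]
                       + phi * (v_r . h_s) + eps)

    with f the per-subject block factors, v_r the ROI's unit fine-geometry
    vector (dotted with per-subject fine factors h_s), g the per-subject
    global offset and eps independent noise.  BOLD series mix the same two
    latent layers with noise::

        ts_r = sqrt(rho_b) * u_b(t) + phi * (v_r . w(t))
               + sqrt(1 - rho_b - phi^2) * eta_r(t)

    so that the mean within-block temporal correlation equals rho_b and
    edge strengths below the block scale follow the fine dot products
    v_i . v_j, which coupled cohorts share across modalities.
    """
    streams = _substreams(config.seed)
    n, R = config.n_subjects, config.n_rois
    rng_b = np.random.default_rng(streams["blocks"])
    mc_blocks = config.resolved_block_map("MC")
    if config.modalities_shared and config.fc_block_map is None:
        fc_blocks = mc_blocks.copy()
    elif config.fc_block_map is None:
        # an independent random partition of the same granularity
        fc_blocks = rng_b.permutation(mc_blocks)
    else:
        fc_blocks = config.resolved_block_map("FC")
    n_blocks = int(max(mc_blocks.max(), fc_blocks.max())) + 1

    # fine-scale similarity geometry: unit row vectors whose pairwise dot
    # products modulate edge strengths below the block scale
    def _fine_vectors() -> np.ndarray:
        v = rng_b.normal(0.0, 1.0, (R, config.fine_dim))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    mc_fine = _fine_vectors()
    fc_fine = mc_fine.copy() if config.modalities_shared else _fine_vectors()
    phi = config.fine_loading

    # per-block longitudinal shifts, shared or independent across modalities
    rng_d = np.random.default_rng(streams["deltas"])
    delta_mc = rng_d.uniform(-1.0, 1.0, n_blocks)
    delta_fc = delta_mc.copy() if config.modalities_shared else rng_d.uniform(-1.0, 1.0, n_blocks)

    lam = config.block_correlation
    rho = config.fc_block_rho
    rho_max = 1.0 - phi**2 - 0.03  # keep unit-variance BOLD mixtures feasible
    mc_loading = {
        "PT:ses1": np.full(n_blocks, lam),
        "PT:ses2": np.clip(lam + config.delta_effect * delta_mc, 0.02, 0.98),
        "FT": np.full(n_blocks, lam),
    }
    fc_rho = {
        "PT:ses1": np.clip(np.full(n_blocks, rho), 0.02, rho_max),
        "PT:ses2": np.clip(rho + config.delta_effect * delta_fc, 0.02, rho_max),
        "FT": np.clip(np.full(n_blocks, rho), 0.02, rho_max),
    }

    # covariates: PT subjects keep identity and GA across sessions
    rng_c = np.random.default_rng(streams["covariates"])
    pt_ids = tuple(f"PT{k:03d}" for k in range(n))
    ft_ids = tuple(f"FT{k:03d}" for k in range(n))
    ga_pt = rng_c.uniform(*GA_RANGES["PT"], n)
    ga_ft = rng_c.uniform(*GA_RANGES["FT"], n)
    pma = {g: rng_c.uniform(*PMA_RANGES[g], n) for g in GROUPS}
    subjects = {"PT:ses1": pt_ids, "PT:ses2": pt_ids, "FT": ft_ids}
    ga = {"PT:ses1": ga_pt, "PT:ses2": ga_pt, "FT": ga_ft}

    cov_rows = []
    for g in GROUPS:
        for s in range(n):
            cov_rows.append(
                {"group": g, "subject_id": subjects[g][s], "pma": pma[g][s], "ga": ga[g][s]}
            )
    covariates = pd.DataFrame(cov_rows)

    # metric tables: fixed regional jitter plus per-group structured draws
    rng_m = np.random.default_rng(streams["metrics"])
    amp = np.array([METRIC_AMPLITUDES[m] for m in METRICS])
    base = np.array([METRIC_BASELINES[m] for m in METRICS])
    jitter = rng_m.normal(0.0, config.roi_jitter_sd, (R, len(METRICS))) * amp  # shared by all groups
    beta_pma = np.array([config.confound_betas[m][0] for m in METRICS])
    beta_ga = np.array([config.confound_betas[m][1] for m in METRICS])

    # ROI labels follow the packaged atlas at the default parcel count so
    # that edge labeling applies directly to synthetic cohorts
    roi_names = tuple(default_atlas().names) if R == 75 else tuple(f"roi{r:02d}" for r in range(R))

    tables: dict[str, CohortMetricTable] = {}
    for g in GROUPS:
        # per-subject latent factors: one per block plus the fine dimensions
        f_block = rng_m.normal(0.0, 1.0, (n, n_blocks))
        f_fine = rng_m.normal(0.0, 1.0, (n, config.fine_dim))
        g_off = rng_m.normal(0.0, config.global_scale_sd, n)
        eps = rng_m.normal(0.0, config.noise_sd, (n, R, len(METRICS)))
        shared_part = (
            mc_loading[g][mc_blocks] * f_block[:, mc_blocks] + phi * (f_fine @ mc_fine.T)
        )
        structured = g_off[:, None, None] + shared_part[:, :, None] + eps
        values = (
            base[None, None, :]
            + jitter[None, :, :]
            + beta_pma[None, None, :] * (pma[g][:, None, None] - PMA_CENTER)
            + beta_ga[None, None, :] * (ga[g][:, None, None] - GA_CENTER)
            + amp[None, None, :] * structured
        )
        tables[g] = CohortMetricTable(
            group=g,
            subjects=subjects[g],
            pma=pma[g],
            ga=ga[g],
            values=values,
            roi_names=roi_names,
        )

    # BOLD series
    rng_t = np.random.default_rng(streams["timeseries"])
    T = config.ts_length
    series: dict[str, list[ROITimeSeriesSet]] = {}
    for g in GROUPS:
        rho_b = fc_rho[g]
        # per-ROI mixing weights over the latent sources (blocks + fine)
        w_block = np.sqrt(rho_b[fc_blocks])
        resid_var = np.clip(1.0 - rho_b[fc_blocks] - phi**2, 0.0, None)
        group_sets = []
        for s in range(n):
            u_block = rng_t.normal(0.0, 1.0, (n_blocks, T))
            u_fine = rng_t.normal(0.0, 1.0, (config.fine_dim, T))
            eta = rng_t.normal(0.0, 1.0, (R, T))
            ts = (
                w_block[:, None] * u_block[fc_blocks]
                + phi * (fc_fine @ u_fine)
                + np.sqrt(resid_var)[:, None] * eta
            )
            group_sets.append(
                ROITimeSeriesSet(
                    subject_id=subjects[g][s],
                    group=g,
                    series=ts,
                    sampling_interval=config.sampling_interval,
                    roi_names=roi_names,
                )
            )
        series[g] = group_sets

    truth = SyntheticTruth(
        mc_blocks=mc_blocks,
        fc_blocks=fc_blocks,
        mc_loading_by_group=mc_loading,
        fc_rho_by_group=fc_rho,
        block_delta_mc=delta_mc,
        block_delta_fc=delta_fc,
        mc_fine=mc_fine,
        fc_fine=fc_fine,
        covariates=covariates,
        confound_betas=dict(config.confound_betas),
        seed=config.seed,
    )
    return CohortDataset(metrics=tables, timeseries=series, truth=truth)
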