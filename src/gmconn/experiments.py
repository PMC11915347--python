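"""Synthetic-recovery and calibration experiments.

These are the package's own validation studies: each one generates data
with known ground truth (or a known null), runs the analysis exactly as
the pipeline would, and measures how well the truth is recovered or how
well a test statistic is calibrated.  They back the acceptance checks and
the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

from . import fc as fc_mod
from . import mc as mc_mod
from . import networks as net_mod
from . import stats as stats_mod
from .delta import delta_fc, delta_mc
from .matrix import ConnectivityMatrix
from .mc import METRICS
from .pipeline import directionality_regressions
from .synthetic import CohortDataset, SyntheticConfig, generate_cohort

__all__ = [
    "confound_recovery",
    "network_recovery",
    "mi_calibration",
    "slope_permutation_calibration",
    "coevolution_discrimination",
    "between_modality_mi_mean",
]


def _corrected_mc(table) -> ConnectivityMatrix:
    return mc_mod.build_mc(mc_mod.minmax_scale(mc_mod.residualize_metrics(table)))


def _block_contrast(matrix: ConnectivityMatrix, blocks: np.ndarray) -> float:
    from .atlas import edge_index_pairs

    pairs = edge_index_pairs(len(blocks))
    within = blocks[pairs[:, 0]] == blocks[pairs[:, 1]]
    e = matrix.upper()
    return float(e[within].mean() - e[~within].mean())


def _recovery_config(seed: int, **overrides) -> SyntheticConfig:
    """The planted-confound recovery conditions: strong 5-block structure
    with a 0.02/week age effect on every metric."""
    betas = {m: (0.02, 0.01) for m in METRICS}
    defaults = dict(
        n_subjects=45,
        n_blocks=5,
        block_correlation=0.8,
        noise_sd=0.1,
        confound_betas=betas,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def confound_recovery(seed: int = 11) -> dict[str, float]:
    """Does residualization remove a planted age effect without erasing the
    planted block structure?

    Returns the worst |corr(metric, PMA)| over ROIs after correction, the
    recovered within-minus-between block contrast, the contrast of an
    identically-seeded cohort with zero confound betas, and the contrast
    obtained when residualization is skipped.
    """
    cfg = _recovery_config(seed)
    ds = generate_cohort(cfg)
    table = ds.metrics["PT:ses1"]
    blocks = ds.truth.mc_blocks

    corrected = mc_mod.residualize_metrics(table)
    worst = 0.0
    for m in range(len(corrected.metrics)):
        for r in range(corrected.n_rois):
            c = np.corrcoef(corrected.values[:, r, m], corrected.pma)[0, 1]
            worst = max(worst, abs(c))

    contrast = _block_contrast(_corrected_mc(table), blocks)
    contrast_nores = _block_contrast(mc_mod.build_mc(mc_mod.minmax_scale(table)), blocks)

    beta0 = dataclasses.replace(cfg, confound_betas={m: (0.0, 0.0) for m in METRICS})
    ds0 = generate_cohort(beta0)
    contrast_beta0 = _block_contrast(_corrected_mc(ds0.metrics["PT:ses1"]), blocks)

    return {
        "max_pma_corr_after_correction": worst,
        "contrast": contrast,
        "contrast_beta0": contrast_beta0,
        "contrast_no_residualization": contrast_nores,
        "n_subjects": cfg.n_subjects,
    }


def network_recovery(seed: int = 12, fc_ts_length: int = 1000) -> dict[str, float]:
    """Ward clustering at the true block count: MI with the planted
    partition relative to the partition's entropy, for both modalities."""
    cfg = _recovery_config(seed, fc_block_rho=0.6, ts_length=fc_ts_length)
    ds = generate_cohort(cfg)
    blocks = ds.truth.mc_blocks
    k = int(blocks.max()) + 1
    h_truth = float(sps.entropy(np.bincount(blocks) / blocks.size))

    mc = _corrected_mc(ds.metrics["PT:ses1"])
    d_mc = net_mod.ward_dendrogram(
        net_mod.corr_to_distance(mc, use_abs=True), mc.roi_names, "MC", "PT:ses1"
    )
    mi_mc = net_mod.mutual_information(d_mc.cut(k), blocks)

    subj = [fc_mod.subject_fc(fc_mod.preprocess_timeseries(t)) for t in ds.timeseries["PT:ses1"]]
    fc = fc_mod.group_fc(subj)
    d_fc = net_mod.ward_dendrogram(
        net_mod.corr_to_distance(fc, use_abs=False), fc.roi_names, "FC", "PT:ses1"
    )
    mi_fc = net_mod.mutual_information(d_fc.cut(k), ds.truth.fc_blocks)

    return {
        "mc_mi_ratio": mi_mc / h_truth,
        "fc_mi_ratio": mi_fc / h_truth,
        "truth_entropy": h_truth,
        "k": k,
    }


def mi_calibration(
    seed: int = 13, n_repeats: int = 500, n_perm: int = 100, n_items: int = 75, k: int = 5
) -> dict[str, float]:
    """False-positive rate of the MI permutation test on independent
    random k-cluster labelings (nominally ~5%)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_repeats):
        a = rng.integers(0, k, n_items)
        b = rng.integers(0, k, n_items)
        obs = net_mod.mutual_information(a, b)
        _, p95 = net_mod.mi_permutation_null(
            a, b, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        hits += obs > p95 + net_mod.MIComparison.TIE_TOL
    return {"significant_fraction": hits / n_repeats, "n_repeats": n_repeats}


def slope_permutation_calibration(
    seed: int = 14, n_repeats: int = 200, n_perm: int = 200, n_edges: int = 2775
) -> dict[str, float]:
    """Uniformity of permutation p-values for the Huber slope under the
    null of independent Gaussian edge vectors (Kolmogorov-Smirnov check)."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_repeats)
    for i in range(n_repeats):
        x = rng.normal(size=n_edges)
        y = rng.normal(size=n_edges)
        fit = stats_mod.permute_slope_p(
            x, y, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[i] = fit.permutation_p
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(pvals.mean()), "n_repeats": n_repeats}


def between_modality_mi_mean(
    ds: CohortDataset, n_perm: int = 100, seed: int = 0
) -> float:
    """Cohort-level MC-vs-FC network overlap: the mean over the three
    groups of the mean significant multi-scale MI (0 when a group has no
    significant cells)."""
    vals = []
    for gi, g in enumerate(mc_mod.GROUPS):
        mc = _corrected_mc(ds.metrics[g])
        subj = [fc_mod.subject_fc(fc_mod.preprocess_timeseries(t)) for t in ds.timeseries[g]]
        fc = fc_mod.group_fc(subj)
        d_mc = net_mod.ward_dendrogram(
            net_mod.corr_to_distance(mc, use_abs=True), mc.roi_names, "MC", g
        )
        d_fc = net_mod.ward_dendrogram(
            net_mod.corr_to_distance(fc, use_abs=False), fc.roi_names, "FC", g
        )
        comp = net_mod.compare_dendrograms(d_mc, d_fc, n_perm=n_perm, seed=seed + gi)
        mean, _, n_sig = net_mod.summarize_mi(comp)
        vals.append(0.0 if n_sig == 0 else mean)
    return float(np.mean(vals))


def _h1_bh_p(ds: CohortDataset, n_perm: int, seed: int) -> tuple[float, float]:
    """BH-adjusted permutation p of the co-evolution regression (dFC on
    dMC) within the six-regression directionality family; returns
    (slope, adjusted p)."""
    mc1 = _corrected_mc(ds.metrics["PT:ses1"]).absolute()
    mc2 = _corrected_mc(ds.metrics["PT:ses2"]).absolute()
    s1 = [fc_mod.subject_fc(fc_mod.preprocess_timeseries(t)) for t in ds.timeseries["PT:ses1"]]
    s2 = [fc_mod.subject_fc(fc_mod.preprocess_timeseries(t)) for t in ds.timeseries["PT:ses2"]]
    fc1, fc2 = fc_mod.group_fc(s1), fc_mod.group_fc(s2)
    dmc = delta_mc(_corrected_mc(ds.metrics["PT:ses1"]), _corrected_mc(ds.metrics["PT:ses2"]))
    dfc = delta_fc(s1, s2)
    table = directionality_regressions(mc1, mc2, fc1, fc2, dmc, dfc, n_perm=n_perm, seed=seed)
    row = table.set_index("regression").loc["dFC~dMC"]
    return float(row["slope"]), float(row["perm_p_bh"])


def coevolution_discrimination(
    seeds: tuple[int, ...] = tuple(range(10)),
    n_perm_slope: int = 200,
    n_perm_mi: int = 100,
) -> dict[str, object]:
    """Can the pipeline tell co-evolving modalities from independent ones?

    For each seed, one cohort with shared block/fine structure and shared
    longitudinal shifts, and one with independent modalities; records
    whether the co-evolution regression is significant (BH p <= 0.05) in
    the coupled cohort and whether its between-modality network overlap
    beats the independent cohort's.
    """
    h1_hits, mi_hits, rows = 0, 0, []
    for seed in seeds:
        coupled = generate_cohort(SyntheticConfig(seed=seed, modalities_shared=True))
        indep = generate_cohort(SyntheticConfig(seed=seed, modalities_shared=False))
        slope, p_bh = _h1_bh_p(coupled, n_perm=n_perm_slope, seed=seed)
        mi_c = between_modality_mi_mean(coupled, n_perm=n_perm_mi, seed=10 * seed)
        mi_i = between_modality_mi_mean(indep, n_perm=n_perm_mi, seed=10 * seed + 5)
        h1_ok = slope > 0 and p_bh <= 0.05
        mi_ok = mi_c > mi_i
        h1_hits += h1_ok
        mi_hits += mi_ok
        rows.append(
            {"seed": seed, "h1_slope": slope, "h1_p_bh": p_bh,
             "mi_coupled": mi_c, "mi_independent": mi_i}
        )
    n = len(seeds)
    return {
        "h1_significant_fraction": h1_hits / n,
        "mi_coupled_higher_fraction": mi_hits / n,
        "per_seed": rows,
        "n_seeds": n,
    }
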