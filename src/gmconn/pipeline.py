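"""End-to-end orchestration: cohort -> MC/FC -> deltas -> edge statistics ->
networks -> multi-scale MI summaries, from one configuration with
deterministic seeding.

The run also evaluates the three directionality hypotheses about
micro-structure/function co-development: (1) co-evolution — the two change
matrices dMC and dFC correlate; (2) microstructure drives function — early
MC predicts dFC and dMC predicts later FC; (3) function drives
microstructure — the mirror-image regressions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import delta as delta_mod
from . import fc as fc_mod
from . import mc as mc_mod
from . import networks as net_mod
from . import stats as stats_mod
from .atlas import ROIAtlas, default_atlas, label_edges, load_atlas
from .matrix import ConnectivityMatrix
from .mc import GROUPS
from .synthetic import CohortDataset, SyntheticConfig, generate_cohort

logger = logging.getLogger("gmconn")

__all__ = [
    "RunConfig",
    "PipelineResults",
    "run_full_analysis",
    "export_circos_edges",
    "directionality_regressions",
]

_STAGES = ("synthetic", "slope_perm", "mi_perm")


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; every option has a recorded default."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    atlas_path: str | None = None
    #: FC preprocessing
    cutoff_hz: float = 0.1
    trim: int = 50
    fisher_z: bool = False
    #: delta construction
    z_mult: float = 1.96
    use_sem: bool = True
    overlap_method: str = "jaccard"
    #: thresholding and tests
    fraction: float = 0.25
    n_perm_slope: int = 1000
    n_perm_mi: int = 100
    k_min: int = 2
    k_max: int = 75
    #: distance conventions per modality
    mc_use_abs: bool = True
    fc_use_abs: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["confound_betas"] = {
            m: list(b) for m, b in self.synthetic.confound_betas.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if syn and "confound_betas" in syn:
            syn["confound_betas"] = {m: tuple(b) for m, b in syn["confound_betas"].items()}
        for key in ("mc_block_map", "fc_block_map"):
            if syn.get(key) is not None:
                syn[key] = tuple(syn[key])
        return cls(synthetic=SyntheticConfig(**syn), **d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)
        }


@dataclass
class PipelineResults:
    """Bundle of everything a full run produced."""

    config: RunConfig
    atlas: ROIAtlas
    mc: dict[str, ConnectivityMatrix]
    mc_abs: dict[str, ConnectivityMatrix]
    fc: dict[str, ConnectivityMatrix]
    subject_fc: dict[str, list[ConnectivityMatrix]]
    dmc: ConnectivityMatrix
    dfc: ConnectivityMatrix
    group_tests: pd.DataFrame
    group_regressions: pd.DataFrame
    mcfc_tables: dict[str, pd.DataFrame]
    slope_comparisons: pd.DataFrame
    directionality: pd.DataFrame
    mi_comparisons: dict[str, net_mod.MIComparison]
    thresholds: dict[str, object]
    summary: dict
    cohort: CohortDataset | None = None

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g, m in self.mc.items():
            m.save_tsv(out / f"mc_{g.replace(':', '-')}.tsv")
        for g, m in self.fc.items():
            m.save_tsv(out / f"fc_{g.replace(':', '-')}.tsv")
        self.dmc.save_tsv(out / "dmc_pt.tsv")
        self.dfc.save_tsv(out / "dfc_pt.tsv")
        self.group_tests.to_csv(out / "group_tests.csv", index=False, float_format="%.17g")
        self.group_regressions.to_csv(
            out / "group_regressions.csv", index=False, float_format="%.17g"
        )
        for g, df in self.mcfc_tables.items():
            df.to_csv(out / f"mcfc_{g.replace(':', '-')}.csv", index=False, float_format="%.17g")
        self.slope_comparisons.to_csv(
            out / "slope_comparisons.csv", index=False, float_format="%.17g"
        )
        self.directionality.to_csv(out / "directionality.csv", index=False, float_format="%.17g")
        for name, comp in self.mi_comparisons.items():
            comp.save_tsv(out / f"mi_{name}.tsv")
        for label, matrix, mask in self.thresholds["edge_masks"]:
            export_circos_edges(matrix, self.atlas, mask).to_csv(
                out / f"edges_{label}.csv", index=False, float_format="%.17g"
            )
        summary_path = out / "summary.json"
        summary_path.write_text(self.summary_json())
        (out / "run_log.txt").write_text(self.summary_log())
        return summary_path

    def summary_json(self) -> str:
        """Canonical JSON serialization of the summary (stable byte-wise)."""
        return json.dumps(self.summary, indent=2, sort_keys=True, default=_json_default) + "\n"

    def summary_log(self) -> str:
        lines = ["gmconn full-analysis run", "resolved options:"]
        for k, v in sorted(self.config.to_dict().items()):
            lines.append(f"  {k}: {v}")
        lines.append(f"stage seeds: {self.config.stage_seeds()}")
        return "\n".join(lines) + "\n"


def export_circos_edges(
    matrix: ConnectivityMatrix, atlas: ROIAtlas, mask: np.ndarray
) -> pd.DataFrame:
    """Edge list (ROI pair, lobes, value, sign) for the kept edges only."""
    edges = matrix.upper()
    labeling = label_edges(atlas)
    if mask.shape != edges.shape:
        raise ValueError("mask does not match the matrix edge count")
    lobes = atlas.table["lobe"].to_numpy()
    names = np.asarray(atlas.names)
    i, j = labeling.pairs[:, 0], labeling.pairs[:, 1]
    df = pd.DataFrame(
        {
            "roi_i": names[i],
            "roi_j": names[j],
            "lobe_i": lobes[i],
            "lobe_j": lobes[j],
            "value": edges,
            "sign": np.sign(edges).astype(int),
        }
    )
    return df[mask].reset_index(drop=True)


def _fit_with_perm(x, y, n_perm, seed):
    return stats_mod.permute_slope_p(x, y, n_perm=n_perm, seed=seed)


def directionality_regressions(
    mc_abs_ses1: ConnectivityMatrix,
    mc_abs_ses2: ConnectivityMatrix,
    fc_ses1: ConnectivityMatrix,
    fc_ses2: ConnectivityMatrix,
    dmc: ConnectivityMatrix,
    dfc: ConnectivityMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """The six robust regressions probing how the two modalities co-develop.

    Hypothesis 1 (co-evolution): dFC on dMC.  Hypothesis 2 (microstructure
    drives function): dFC on MC at each session, and later FC on dMC.
    Hypothesis 3 (function drives microstructure): dMC on early FC, and
    later MC on dFC.  Permutation p-values are BH-adjusted across the
    family.
    """
    e = {
        "dMC": dmc.upper(), "dFC": dfc.upper(),
        "MC1": mc_abs_ses1.upper(), "MC2": mc_abs_ses2.upper(),
        "FC1": fc_ses1.upper(), "FC2": fc_ses2.upper(),
    }
    hyp_regs = [
        ("h1", "dFC~dMC", "dMC", "dFC"),
        ("h2", "dFC~MC1", "MC1", "dFC"),
        ("h2", "FC2~dMC", "dMC", "FC2"),
        ("h3", "dMC~FC1", "FC1", "dMC"),
        ("h3", "MC2~dFC", "dFC", "MC2"),
        ("h2", "dFC~MC2", "MC2", "dFC"),
    ]
    rows = []
    for i, (hyp, label, xp, yp) in enumerate(hyp_regs):
        fit = _fit_with_perm(e[xp], e[yp], n_perm, seed + i)
        rows.append(
            {"hypothesis": hyp, "regression": label, "slope": fit.slope,
             "intercept": fit.intercept, "slope_se": fit.slope_se,
             "perm_p": fit.permutation_p}
        )
    table = pd.DataFrame(rows)
    table["perm_p_bh"] = stats_mod.bh_fdr(table["perm_p"].to_numpy())
    return table


def run_full_analysis(config: RunConfig) -> PipelineResults:
    """Run every stage on a synthetic cohort defined by the configuration."""
    seeds = config.stage_seeds()
    atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
    labeling = label_edges(atlas)
    syn = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
    logger.info("generating synthetic cohort (seed %d)", syn.seed)
    cohort = generate_cohort(syn)

    # --- MC per group ----------------------------------------------------
    mc: dict[str, ConnectivityMatrix] = {}
    for g in GROUPS:
        table = mc_mod.minmax_scale(mc_mod.residualize_metrics(cohort.metrics[g]))
        mc[g] = mc_mod.build_mc(table, atlas if syn.n_rois == atlas.n_rois else None)
    mc_abs = {g: mc_mod.absolute_mc(m) for g, m in mc.items()}

    # --- FC per group ----------------------------------------------------
    fc: dict[str, ConnectivityMatrix] = {}
    subject_fc: dict[str, list[ConnectivityMatrix]] = {}
    for g in GROUPS:
        mats = []
        for ts in cohort.timeseries[g]:
            pre = fc_mod.preprocess_timeseries(ts, cutoff_hz=config.cutoff_hz, trim=config.trim)
            mats.append(fc_mod.subject_fc(pre))
        subject_fc[g] = mats
        fc[g] = fc_mod.group_fc(mats, fisher_z=config.fisher_z)

    # --- group comparisons (paired over edges) ---------------------------
    test_rows, reg_rows = [], []
    comparisons = [("PT:ses2", "PT:ses1"), ("PT:ses2", "FT")]
    slope_fits: dict[str, stats_mod.RobustFitResult] = {}
    for mod_name, mats in (("MC", mc_abs), ("FC", fc)):
        for ga, gb in comparisons:
            va, vb = mats[ga].upper(), mats[gb].upper()
            res = stats_mod.paired_wilcoxon(va, vb)
            test_rows.append(
                {"modality": mod_name, "group_a": ga, "group_b": gb, "W": res.statistic,
                 "p": res.p_value, "n_pairs": res.n_pairs, "direction": res.direction}
            )
            fit = _fit_with_perm(vb, va, config.n_perm_slope, seeds["slope_perm"] + len(reg_rows))
            reg_rows.append(
                {"modality": mod_name, "response": ga, "predictor": gb, "slope": fit.slope,
                 "intercept": fit.intercept, "slope_se": fit.slope_se,
                 "perm_p": fit.permutation_p, "n_perm": config.n_perm_slope}
            )
    group_tests = pd.DataFrame(test_rows)
    group_regressions = pd.DataFrame(reg_rows)

    # --- MC-FC coupling per group, by connection subset ------------------
    mcfc_tables = {}
    for gi, g in enumerate(GROUPS):
        mcfc_tables[g] = stats_mod.subset_regression_report(
            mc_abs[g], fc[g], labeling,
            n_perm=config.n_perm_slope, seed=seeds["slope_perm"] + 100 + 10 * gi,
        )
        wb = mcfc_tables[g].set_index("subset").loc["whole-brain"]
        slope_fits[g] = stats_mod.RobustFitResult(
            slope=float(wb["slope"]), intercept=float(wb["intercept"]),
            slope_se=float(wb["slope_se"]), n_edges=int(wb["n_edges"]),
        )

    slope_rows = []
    for ga, gb in (("PT:ses1", "PT:ses2"), ("PT:ses2", "FT")):
        z, p = stats_mod.compare_slopes_z(slope_fits[ga], slope_fits[gb])
        slope_rows.append({"group_a": ga, "group_b": gb, "Z": z, "p": p})
    slope_comparisons = pd.DataFrame(slope_rows)

    # --- developmental change --------------------------------------------
    dmc = delta_mod.delta_mc(mc["PT:ses1"], mc["PT:ses2"])
    dfc = delta_mod.delta_fc(
        subject_fc["PT:ses1"], subject_fc["PT:ses2"],
        z_mult=config.z_mult, use_sem=config.use_sem, overlap_method=config.overlap_method,
    )

    # --- directionality hypotheses (predictor -> response) ---------------
    directionality = directionality_regressions(
        mc_abs["PT:ses1"], mc_abs["PT:ses2"], fc["PT:ses1"], fc["PT:ses2"],
        dmc, dfc, n_perm=config.n_perm_slope, seed=seeds["slope_perm"] + 200,
    )

    # --- networks and multi-scale MI -------------------------------------
    k_range = range(config.k_min, min(config.k_max, atlas.n_rois) + 1)
    roi_names = mc["PT:ses1"].roi_names
    dendro: dict[str, net_mod.Dendrogram] = {}
    for g in GROUPS:
        dendro[f"MC:{g}"] = net_mod.ward_dendrogram(
            net_mod.corr_to_distance(mc[g], use_abs=config.mc_use_abs), roi_names, "MC", g
        )
        dendro[f"FC:{g}"] = net_mod.ward_dendrogram(
            net_mod.corr_to_distance(fc[g], use_abs=config.fc_use_abs), roi_names, "FC", g
        )
    dendro["dMC"] = net_mod.ward_dendrogram(
        net_mod.corr_to_distance(dmc, use_abs=False), roi_names, "dMC", "PT"
    )
    dendro["dFC"] = net_mod.ward_dendrogram(
        net_mod.corr_to_distance(dfc, use_abs=False), roi_names, "dFC", "PT"
    )

    pairs = [
        # within-modality, between groups
        ("MC_ses1_vs_ses2", "MC:PT:ses1", "MC:PT:ses2"),
        ("MC_ses2_vs_FT", "MC:PT:ses2", "MC:FT"),
        ("FC_ses1_vs_ses2", "FC:PT:ses1", "FC:PT:ses2"),
        ("FC_ses2_vs_FT", "FC:PT:ses2", "FC:FT"),
        # between modalities, within group
        ("MCFC_ses1", "MC:PT:ses1", "FC:PT:ses1"),
        ("MCFC_ses2", "MC:PT:ses2", "FC:PT:ses2"),
        ("MCFC_FT", "MC:FT", "FC:FT"),
        # longitudinal networks and the directionality comparisons
        ("dMC_vs_dFC", "dMC", "dFC"),
        ("dFC_vs_MC_ses1", "dFC", "MC:PT:ses1"),
        ("dFC_vs_MC_ses2", "dFC", "MC:PT:ses2"),
        ("dMC_vs_FC_ses1", "dMC", "FC:PT:ses1"),
        ("dMC_vs_FC_ses2", "dMC", "FC:PT:ses2"),
    ]
    mi_comparisons = {}
    for i, (name, ka, kb) in enumerate(pairs):
        mi_comparisons[name] = net_mod.compare_dendrograms(
            dendro[ka], dendro[kb], k_range=k_range,
            n_perm=config.n_perm_mi, seed=seeds["mi_perm"] + i, name=name,
        )

    # --- thresholded edge lists ------------------------------------------
    mc_list = [mc_abs[g] for g in GROUPS]
    fc_list = [fc[g] for g in GROUPS]
    thr_common_mc, masks_common_mc = stats_mod.threshold_top_fraction(
        mc_list, fraction=config.fraction, mode="common"
    )
    thr_adapt_mc, masks_adapt_mc = stats_mod.threshold_top_fraction(
        mc_list, fraction=config.fraction, mode="adapted"
    )
    thr_common_fc, masks_common_fc = stats_mod.threshold_top_fraction(
        fc_list, fraction=config.fraction, mode="common"
    )
    thr_adapt_fc, masks_adapt_fc = stats_mod.threshold_top_fraction(
        fc_list, fraction=config.fraction, mode="adapted"
    )
    thr_delta, masks_delta = stats_mod.threshold_top_fraction(
        [dmc.absolute(), dfc.absolute()], fraction=config.fraction, mode="adapted"
    )
    edge_masks = []
    for gi, g in enumerate(GROUPS):
        tag = g.replace(":", "-")
        edge_masks.append((f"mc_common_{tag}", mc[g], masks_common_mc[gi]))
        edge_masks.append((f"mc_adapted_{tag}", mc[g], masks_adapt_mc[gi]))
        edge_masks.append((f"fc_common_{tag}", fc[g], masks_common_fc[gi]))
        edge_masks.append((f"fc_adapted_{tag}", fc[g], masks_adapt_fc[gi]))
    edge_masks.append(("dmc", dmc, masks_delta[0]))
    edge_masks.append(("dfc", dfc, masks_delta[1]))
    thresholds = {
        "mc_common": thr_common_mc[0],
        "mc_adapted": dict(zip(GROUPS, thr_adapt_mc)),
        "fc_common": thr_common_fc[0],
        "fc_adapted": dict(zip(GROUPS, thr_adapt_fc)),
        "dmc_adapted": thr_delta[0],
        "dfc_adapted": thr_delta[1],
        "edge_masks": edge_masks,
    }

    # --- machine-readable summary ----------------------------------------
    mi_summary = {}
    for name, comp in mi_comparisons.items():
        mean, sd, n_sig = net_mod.summarize_mi(comp)
        mi_summary[name] = {
            "mean_significant": None if np.isnan(mean) else mean,
            "sd_significant": None if np.isnan(sd) else sd,
            "n_significant": n_sig,
            "n_perm": comp.n_perm,
        }
    summary = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "group_tests": group_tests.to_dict(orient="records"),
        "group_regressions": group_regressions.to_dict(orient="records"),
        "mcfc_whole_brain_slopes": {
            g: {"slope": slope_fits[g].slope, "slope_se": slope_fits[g].slope_se,
                "perm_p": float(mcfc_tables[g].set_index("subset").loc["whole-brain", "perm_p"])}
            for g in GROUPS
        },
        "slope_comparisons": slope_comparisons.to_dict(orient="records"),
        "directionality": directionality.to_dict(orient="records"),
        "mi": mi_summary,
        "thresholds": {k: v for k, v in thresholds.items() if k != "edge_masks"},
    }
    return PipelineResults(
        config=config, atlas=atlas, mc=mc, mc_abs=mc_abs, fc=fc, subject_fc=subject_fc,
        dmc=dmc, dfc=dfc, group_tests=group_tests, group_regressions=group_regressions,
        mcfc_tables=mcfc_tables, slope_comparisons=slope_comparisons,
        directionality=directionality, mi_comparisons=mi_comparisons,
        thresholds=thresholds, summary=summary, cohort=cohort,
    )
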