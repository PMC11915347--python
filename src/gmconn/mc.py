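"""Group-wise microstructural connectivity (MC) from regional diffusion metrics.

MC treats each ROI as a "microstructural fingerprint": the six regional
diffusion metrics (FA, AD, RD, MD from the tensor model; NDI, ODI from
NODDI) of every subject in a group, concatenated into one vector per ROI.
The MC edge between two ROIs is the Pearson correlation of their
fingerprints.  Before correlation the metric table is residualized for
per-subject confounds (post-menstrual age at scan, gestational age at
birth, and a residual global median of the metric) and min-max scaled per
metric over the pooled group values, so that edges reflect between-region
covariation rather than global maturation or head-size effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .matrix import ConnectivityMatrix

METRICS = ("FA", "AD", "RD", "MD", "NDI", "ODI")
#: metrics that are dimensionless fractions in [0, 1]
UNIT_INTERVAL_METRICS = ("FA", "NDI", "ODI")
#: diffusivities in mm^2/s, strictly positive in tissue
DIFFUSIVITY_METRICS = ("AD", "RD", "MD")

GROUPS = ("PT:ses1", "PT:ses2", "FT")

__all__ = [
    "METRICS",
    "GROUPS",
    "CohortMetricTable",
    "compute_global_covariate",
    "residualize_metrics",
    "minmax_scale",
    "build_mc",
    "absolute_mc",
]


@dataclass(frozen=True)
class CohortMetricTable:
    """Subjects x ROIs x metrics for one infant group, plus age covariates.

    ``values[s, r, m]`` holds metric ``metrics[m]`` of subject ``s`` in ROI
    ``r``; ``pma`` is post-menstrual age at scan and ``ga`` gestational age
    at birth, both in weeks.
    """

    group: str
    subjects: tuple[str, ...]
    pma: np.ndarray
    ga: np.ndarray
    values: np.ndarray = field(repr=False)
    roi_names: tuple[str, ...]
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self) -> None:
        n, r, m = len(self.subjects), len(self.roi_names), len(self.metrics)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "pma", np.asarray(self.pma, dtype=float))
        object.__setattr__(self, "ga", np.asarray(self.ga, dtype=float))
        if v.shape != (n, r, m):
            raise ValueError(f"values shape {v.shape} != ({n}, {r}, {m})")
        if self.pma.shape != (n,) or self.ga.shape != (n,):
            raise ValueError("pma/ga must have one entry per subject")
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if not np.isfinite(v).all():
            raise ValueError("metric table contains missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def metric_index(self, metric: str) -> int:
        try:
            return self.metrics.index(metric)
        except ValueError:
            raise KeyError(f"unknown metric {metric!r}") from None

    def check_physical_ranges(self) -> list[str]:
        """Report metrics whose raw values leave their physical range.

        FA/NDI/ODI live in [0, 1] and diffusivities are positive in real
        data; synthetic tables with planted confound effects may violate
        this harmlessly, so violations are reported, not raised.
        """
        problems = []
        for m in UNIT_INTERVAL_METRICS:
            if m in self.metrics:
                x = self.values[:, :, self.metric_index(m)]
                if x.min() < 0 or x.max() > 1:
                    problems.append(f"{m} outside [0, 1]")
        for m in DIFFUSIVITY_METRICS:
            if m in self.metrics:
                if self.values[:, :, self.metric_index(m)].min() <= 0:
                    problems.append(f"{m} not strictly positive")
        return problems

    # -- long-format CSV round trip --------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        n, r, m = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.roi_names, self.metrics],
            names=["subject_id", "roi_name", "metric"],
        )
        df = pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()
        df.insert(0, "group", self.group)
        cov = dict(zip(self.subjects, zip(self.pma, self.ga)))
        df["pma_scan_weeks"] = df["subject_id"].map(lambda s: cov[s][0])
        df["ga_birth_weeks"] = df["subject_id"].map(lambda s: cov[s][1])
        return df[
            ["group", "subject_id", "pma_scan_weeks", "ga_birth_weeks", "roi_name", "metric", "value"]
        ]

    def save_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, group: str) -> "CohortMetricTable":
        sub = df[df["group"] == group]
        if sub.empty:
            raise ValueError(f"no rows for group {group!r}")
        subjects = tuple(dict.fromkeys(sub["subject_id"]))
        roi_names = tuple(dict.fromkeys(sub["roi_name"]))
        metrics = tuple(dict.fromkeys(sub["metric"]))
        pivot = sub.set_index(["subject_id", "roi_name", "metric"])["value"]
        values = pivot.to_numpy().reshape(len(subjects), len(roi_names), len(metrics))
        cov = sub.drop_duplicates("subject_id").set_index("subject_id")
        return cls(
            group=group,
            subjects=subjects,
            pma=cov.loc[list(subjects), "pma_scan_weeks"].to_numpy(),
            ga=cov.loc[list(subjects), "ga_birth_weeks"].to_numpy(),
            values=values,
            roi_names=roi_names,
            metrics=metrics,
        )

    @classmethod
    def load_csv(cls, path: str | Path, group: str) -> "CohortMetricTable":
        return cls.from_long_frame(pd.read_csv(path), group)


def _ols_residuals(X: np.ndarray, y: np.ndarray, column_names: list[str]) -> np.ndarray:
    """Residuals of an OLS fit, raising on a rank-deficient design."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns among {column_names}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def compute_global_covariate(table: CohortMetricTable, metric: str) -> np.ndarray:
    """Per-subject residual of the global median metric, corrected for age.

    The global measure is the median of ``metric`` over all ROIs of each
    subject; its residual from an OLS fit on [1, PMA, GA] across subjects
    of the group captures subject-level global offsets (e.g., overall
    tissue water content) orthogonal to age.
    """
    med = np.median(table.values[:, :, table.metric_index(metric)], axis=1)
    X = np.column_stack([np.ones(table.n_subjects), table.pma, table.ga])
    return _ols_residuals(X, med, ["intercept", "PMA", "GA"])


def residualize_metrics(table: CohortMetricTable, include_global: bool = True) -> CohortMetricTable:
    """Remove per-subject confounds from every (ROI, metric) column.

    Each column is replaced by its residual from a single joint OLS on
    [1, PMA, GA, global-covariate(metric)] across the subjects of the
    group; residuals are exactly orthogonal to every regressor.
    """
    n_regressors = 4 if include_global else 3
    if table.n_subjects < n_regressors + 1:
        raise ValueError(
            f"residualization needs at least {n_regressors + 1} subjects, got {table.n_subjects}"
        )
    out = np.empty_like(table.values)
    base = [np.ones(table.n_subjects), table.pma, table.ga]
    names = ["intercept", "PMA", "GA"]
    for m, metric in enumerate(table.metrics):
        cols, colnames = list(base), list(names)
        if include_global:
            cols.append(compute_global_covariate(table, metric))
            colnames.append(f"global_{metric}")
        X = np.column_stack(cols)
        out[:, :, m] = _ols_residuals(X, table.values[:, :, m], colnames)
    return replace(table, values=out)


def minmax_scale(table: CohortMetricTable) -> CohortMetricTable:
    """Scale each metric to [0, 1] over the pooled (subjects x ROIs) values."""
    out = np.empty_like(table.values)
    for m, metric in enumerate(table.metrics):
        x = table.values[:, :, m]
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            raise ValueError(f"metric {metric!r} is constant; min-max scale undefined")
        out[:, :, m] = (x - lo) / (hi - lo)
    return replace(table, values=out)


def build_mc(table: CohortMetricTable, atlas: ROIAtlas | None = None) -> ConnectivityMatrix:
    """Pearson correlation of regional fingerprints -> signed group MC.

    The fingerprint of an ROI is its (subjects x metrics) block flattened
    subject-major (subject 1's six metrics, then subject 2's, ...); any
    fixed order gives the same correlations as long as it is common to all
    ROIs.
    """
    if table.n_subjects < 2:
        raise ValueError("MC needs at least 2 subjects")
    if atlas is not None and tuple(atlas.names) != table.roi_names:
        raise ValueError("metric table ROI order does not match the atlas")
    # (R, n_subjects * n_metrics), subject-major within each row
    fingerprints = np.transpose(table.values, (1, 0, 2)).reshape(table.n_rois, -1)
    dead = np.flatnonzero(np.ptp(fingerprints, axis=1) == 0)
    if dead.size:
        raise ValueError(f"zero-variance fingerprint for ROI {table.roi_names[dead[0]]!r}")
    mc = np.corrcoef(fingerprints)
    mc = np.clip((mc + mc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mc, 1.0)
    return ConnectivityMatrix("MC", table.group, mc, table.roi_names, signed=True)


def absolute_mc(mc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise absolute MC, used in group comparisons."""
    if mc.modality != "MC":
        raise ValueError("absolute_mc expects an MC matrix")
    return mc.absolute()
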