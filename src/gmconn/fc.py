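"""Functional connectivity (FC) from regional BOLD time series.

Subject-level FC is the Pearson correlation between the preprocessed
median BOLD series of each ROI pair; group FC is the plain average of
subject matrices (optionally through Fisher's z).  Preprocessing follows
the ROI-series pipeline: zero-phase low-pass filtering at 0.1 Hz,
z-scoring, and trimming of the first and last 50 samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .matrix import ConnectivityMatrix

MIN_RETAINED = 50  # Pearson r is unstable on shorter series

__all__ = ["ROITimeSeriesSet", "preprocess_timeseries", "subject_fc", "group_fc", "MIN_RETAINED"]


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Regional BOLD series of one subject: ``series[roi, t]`` in atlas order."""

    subject_id: str
    group: str
    series: np.ndarray = field(repr=False)
    sampling_interval: float
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        object.__setattr__(self, "series", s)
        if s.ndim != 2 or s.shape[0] != len(self.roi_names):
            raise ValueError(f"series shape {s.shape} does not match {len(self.roi_names)} ROIs")
        if not np.isfinite(s).all():
            raise ValueError("time series contain non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]

    # -- TSV + sidecar JSON round trip -----------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.series, index=self.roi_names).to_csv(
            path, sep="\t", header=False, float_format="%.17g"
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "subject_id": self.subject_id,
                    "group": self.group,
                    "sampling_interval": self.sampling_interval,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ROITimeSeriesSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls(
            subject_id=meta["subject_id"],
            group=meta["group"],
            series=df.to_numpy(dtype=float),
            sampling_interval=float(meta["sampling_interval"]),
            roi_names=tuple(df.index),
        )


def preprocess_timeseries(
    ts: ROITimeSeriesSet, cutoff_hz: float = 0.1, trim: int = 50
) -> ROITimeSeriesSet:
    """Low-pass filter, z-score, and trim a regional time-series set.

    The filter is a 4th-order Butterworth applied forward-backward
    (zero phase), so a common pure delay between two ROIs cannot induce
    lag-driven decorrelation.  Z-scoring uses the mean and SD of the
    retained (post-trim) support, so retained series have exactly zero
    mean and unit SD.
    """
    nyquist = 0.5 / ts.sampling_interval
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.4g} Hz")
    retained = ts.n_timepoints - 2 * trim
    if retained < MIN_RETAINED:
        raise ValueError(
            f"only {retained} samples would remain after trimming {trim} at each end; "
            f"need at least {MIN_RETAINED}"
        )
    sos = signal.butter(4, cutoff_hz, btype="low", fs=1.0 / ts.sampling_interval, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.series, axis=1)
    keep = filtered[:, trim : ts.n_timepoints - trim] if trim else filtered
    mu = keep.mean(axis=1, keepdims=True)
    sd = keep.std(axis=1, keepdims=True)
    dead = np.flatnonzero(sd.ravel() <= 1e-12 * (1.0 + np.abs(mu.ravel())))
    if dead.size:
        raise ValueError(f"ROI {ts.roi_names[dead[0]]!r} has zero variance after filtering")
    return replace(ts, series=(keep - mu) / sd)


def subject_fc(ts: ROITimeSeriesSet) -> ConnectivityMatrix:
    """75x75 Pearson matrix of one subject's preprocessed series."""
    dead = np.flatnonzero(np.ptp(ts.series, axis=1) == 0)
    if dead.size:
        raise ValueError(f"ROI {ts.roi_names[dead[0]]!r} has zero variance")
    fc = np.corrcoef(ts.series)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return ConnectivityMatrix(
        "FC", ts.group, fc, ts.roi_names, signed=True, subject_id=ts.subject_id
    )


def group_fc(matrices: list[ConnectivityMatrix], fisher_z: bool = False) -> ConnectivityMatrix:
    """Average subject FC matrices into a group matrix.

    With ``fisher_z`` the average runs through arctanh/tanh; the default is
    a plain arithmetic mean of correlation values.
    """
    if not matrices:
        raise ValueError("group_fc needs at least one subject matrix")
    roi_names = matrices[0].roi_names
    group = matrices[0].group
    for m in matrices:
        if m.roi_names != roi_names:
            raise ValueError(f"subject {m.subject_id!r} has a mismatched ROI order")
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix("FC", group, mean, roi_names, signed=True)
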