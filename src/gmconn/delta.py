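"""Developmental-change matrices between the two preterm sessions.

``delta_mc`` is the plain difference of absolute MC (the metric tables are
already age-residualized within each group, so no further weighting is
applied).  ``delta_fc`` shrinks the raw difference of group-mean FC by the
overlap of per-edge confidence intervals of the group means, so that edges
whose apparent change is within sampling variability are damped while the
sign always records the direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import upper_triangle
from .matrix import ConnectivityMatrix

__all__ = ["EdgeCI", "edge_ci", "ci_overlap_weight", "delta_mc", "delta_fc"]


@dataclass(frozen=True)
class EdgeCI:
    """Per-edge interval for the group-mean connectivity strength."""

    center: np.ndarray
    half_width: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        h = np.asarray(self.half_width, dtype=float)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "half_width", h)
        if c.shape != h.shape:
            raise ValueError("center and half_width must have identical shapes")
        if (h < 0).any():
            raise ValueError("half_width must be non-negative")

    @property
    def lower(self) -> np.ndarray:
        return self.center - self.half_width

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.half_width


def _edge_stack(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    roi_names = matrices[0].roi_names
    for m in matrices:
        if m.roi_names != roi_names:
            raise ValueError("subject matrices have mismatched ROI orders")
    return np.stack([m.upper() for m in matrices])


def edge_ci(
    subject_matrices: list[ConnectivityMatrix],
    z_mult: float = 1.96,
    use_sem: bool = True,
) -> EdgeCI:
    """Confidence interval of the group mean for every edge.

    ``half_width = z_mult * SD / sqrt(n)`` by default (a 95% mean CI at
    z_mult 1.96); ``use_sem=False`` drops the 1/sqrt(n), giving a
    dispersion interval instead.
    """
    if len(subject_matrices) < 3:
        raise ValueError(f"need at least 3 subjects for an edge CI, got {len(subject_matrices)}")
    stack = _edge_stack(subject_matrices)
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1)
    half = z_mult * sd / np.sqrt(n) if use_sem else z_mult * sd
    return EdgeCI(center=stack.mean(axis=0), half_width=half, n_subjects=n)


def ci_overlap_weight(ci_a: EdgeCI, ci_b: EdgeCI, method: str = "jaccard") -> np.ndarray:
    """Weight in [0, 1] per edge: 1 - interval overlap.

    ``jaccard`` measures overlap as intersection length over union length;
    ``min`` divides by the shorter interval instead.  Two identical
    degenerate intervals overlap fully (weight 0); disjoint intervals get
    full weight 1.
    """
    lo = np.maximum(ci_a.lower, ci_b.lower)
    hi = np.minimum(ci_a.upper, ci_b.upper)
    inter = np.clip(hi - lo, 0.0, None)
    if method == "jaccard":
        denom = np.maximum(ci_a.upper, ci_b.upper) - np.minimum(ci_a.lower, ci_b.lower)
    elif method == "min":
        denom = np.minimum(2 * ci_a.half_width, 2 * ci_b.half_width)
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    # both intervals degenerate: full overlap iff equal points
    degenerate = (ci_a.half_width == 0) & (ci_b.half_width == 0)
    overlap = np.where(degenerate, (ci_a.center == ci_b.center).astype(float), overlap)
    return 1.0 - overlap


def delta_mc(mc_ses1: ConnectivityMatrix, mc_ses2: ConnectivityMatrix) -> ConnectivityMatrix:
    """Difference of absolute MC: positive entries mean strengthening."""
    if mc_ses1.modality != "MC" or mc_ses2.modality != "MC":
        raise ValueError("delta_mc expects two MC matrices")
    if mc_ses1.roi_names != mc_ses2.roi_names:
        raise ValueError("MC matrices have mismatched ROI orders")
    d = np.abs(mc_ses2.values) - np.abs(mc_ses1.values)
    np.fill_diagonal(d, 0.0)
    return ConnectivityMatrix("dMC", "PT:ses2-ses1", d, mc_ses1.roi_names, signed=True)


def delta_fc(
    fc_stack_ses1: list[ConnectivityMatrix],
    fc_stack_ses2: list[ConnectivityMatrix],
    z_mult: float = 1.96,
    use_sem: bool = True,
    overlap_method: str = "jaccard",
) -> ConnectivityMatrix:
    """CI-overlap-weighted signed difference of group-mean FC.

    Per edge: ``d = mean_ses2 - mean_ses1`` shrunk by ``1 - overlap`` of
    the two mean CIs; heavily overlapping intervals (change within noise)
    push the entry toward zero.  Exactly antisymmetric under session swap.
    """
    ci1 = edge_ci(fc_stack_ses1, z_mult=z_mult, use_sem=use_sem)
    ci2 = edge_ci(fc_stack_ses2, z_mult=z_mult, use_sem=use_sem)
    roi_names = fc_stack_ses1[0].roi_names
    if fc_stack_ses2[0].roi_names != roi_names:
        raise ValueError("the two sessions have mismatched ROI orders")
    weight = ci_overlap_weight(ci1, ci2, method=overlap_method)
    edges = (ci2.center - ci1.center) * weight
    return ConnectivityMatrix.from_edges(edges, "dFC", "PT:ses2-ses1", roi_names, diagonal=0.0)
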