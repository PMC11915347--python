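"""Hierarchical "networks" from connectivity matrices and their overlap.

ROIs with similar connectivity profiles are grouped by Ward clustering of
the cosine-theorem distance d = sqrt(2 (1 - rho)) — the Euclidean distance
between standardized profiles with correlation rho.  Because no single
cluster count is privileged in the developing brain, two dendrograms are
compared over *all* cluster-size pairs (2..R): the mutual information of
every cut pair is tested against a permutation null (shuffled cluster
assignments), and only cells beating the null's 95th percentile
contribute to the summary overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.special import xlogy

from .matrix import ConnectivityMatrix

__all__ = [
    "Dendrogram",
    "MIComparison",
    "corr_to_distance",
    "ward_dendrogram",
    "cut_dendrogram",
    "mutual_information",
    "mi_across_scales",
    "mi_permutation_null",
    "compare_dendrograms",
    "summarize_mi",
]


def corr_to_distance(matrix: ConnectivityMatrix, use_abs: bool) -> np.ndarray:
    """Cosine-theorem distance matrix from correlations.

    ``use_abs`` folds the sign first (used for MC, where strong negative
    covariation still marks related regions); FC keeps signed values.
    """
    rho = np.abs(matrix.values) if use_abs else matrix.values.copy()
    if np.abs(rho).max() > 1 + 1e-8:
        raise ValueError("correlations outside [-1, 1]")
    rho = np.clip(rho, -1.0, 1.0)
    d = np.sqrt(np.clip(2.0 * (1.0 - rho), 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Ward linkage over the ROIs of one connectivity matrix."""

    linkage_matrix: np.ndarray = field(repr=False)
    roi_names: tuple[str, ...]
    modality: str
    group: str
    distance: str = "cosine-theorem"

    def __post_init__(self) -> None:
        z = np.asarray(self.linkage_matrix, dtype=float)
        object.__setattr__(self, "linkage_matrix", z)
        r = len(self.roi_names)
        if z.shape != (r - 1, 4):
            raise ValueError(f"linkage shape {z.shape} inconsistent with {r} leaves")
        if np.any(np.diff(z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.roi_names)

    def cut(self, k: int) -> np.ndarray:
        return cut_dendrogram(self, k)

    # -- merge-table CSV round trip --------------------------------------
    def to_merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "step": np.arange(len(z)),
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "height": z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_merge_table().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load_csv(
        cls, path: str | Path, roi_names: tuple[str, ...], modality: str, group: str
    ) -> "Dendrogram":
        df = pd.read_csv(path)
        z = np.column_stack([df["left"], df["right"], df["height"], df["size"]]).astype(float)
        return cls(z, tuple(roi_names), modality, group)


def ward_dendrogram(
    distance: np.ndarray,
    roi_names: tuple[str, ...],
    modality: str = "MC",
    group: str = "",
) -> Dendrogram:
    """Ward linkage on a full distance matrix (deterministic)."""
    d = np.asarray(distance, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite values")
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"expected a square distance matrix, got shape {d.shape}")
    if np.abs(d - d.T).max() > 1e-10:
        raise ValueError("distance matrix must be symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="ward")
    return Dendrogram(z, tuple(roi_names), modality, group)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Exactly k non-empty clusters, labeled by merge order (nested cuts)."""
    r = dendrogram.n_leaves
    if not 1 <= k <= r:
        raise ValueError(f"k must lie in 1..{r}, got {k}")
    return cut_tree(dendrogram.linkage_matrix, n_clusters=k).ravel()


@lru_cache(maxsize=8)
def _plogp_table(n: int) -> np.ndarray:
    """(c/n) * log(c/n) for integer counts c = 0..n (0 log 0 = 0)."""
    c = np.arange(n + 1, dtype=float)
    return xlogy(c / n, c / n)


def mutual_information(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """MI (nats) between two labelings via their contingency table.

    Computed as H(a) + H(b) - H(a, b) with exactly the same floating-point
    operations as the permutation null, so that a shuffle that happens to
    reproduce the observed table yields a bitwise-identical MI (ties in the
    null are then resolved correctly by the strict comparison).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("labelings must be non-empty and equally long")
    a = np.unique(a, return_inverse=True)[1]
    b = np.unique(b, return_inverse=True)[1]
    ka, kb = a.max() + 1, b.max() + 1
    n = a.size
    xl = _plogp_table(n)
    h_joint = -xl[np.bincount(a * kb + b, minlength=ka * kb)].sum()
    h_a = -xl[np.bincount(a, minlength=ka)].sum()
    h_b = -xl[np.bincount(b, minlength=kb)].sum()
    return float(h_a + h_b - h_joint)


def mi_across_scales(
    d_a: Dendrogram, d_b: Dendrogram, k_range: range = range(2, 76)
) -> np.ndarray:
    """MI between every cut pair (k_a, k_b) of two dendrograms."""
    if d_a.n_leaves != d_b.n_leaves:
        raise ValueError("dendrograms must share a leaf set")
    cuts_a = {k: d_a.cut(k) for k in k_range}
    cuts_b = {k: d_b.cut(k) for k in k_range}
    ks = list(k_range)
    mi = np.empty((len(ks), len(ks)))
    for i, ka in enumerate(ks):
        for j, kb in enumerate(ks):
            mi[i, j] = mutual_information(cuts_a[ka], cuts_b[kb])
    return mi


def _null_mi_sample(
    labels_a: np.ndarray, labels_b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """MI for ``n_perm`` shuffles of labels_b (cluster sizes preserved)."""
    a = np.unique(labels_a, return_inverse=True)[1]
    b = np.unique(labels_b, return_inverse=True)[1]
    ka, kb = a.max() + 1, b.max() + 1
    n = a.size
    perms = rng.permuted(np.tile(b, (n_perm, 1)), axis=1)
    flat = (np.arange(n_perm)[:, None] * (ka * kb) + a[None, :] * kb + perms).ravel()
    counts = np.bincount(flat, minlength=n_perm * ka * kb).reshape(n_perm, ka * kb)
    # MI = H(a) + H(b) - H(a, b); the margins are permutation-invariant
    xl = _plogp_table(n)
    h_joint = -xl[counts].sum(axis=1)
    h_a = -xl[np.bincount(a, minlength=ka)].sum()
    h_b = -xl[np.bincount(b, minlength=kb)].sum()
    return h_a + h_b - h_joint


def _nearest_rank_p95(sample: np.ndarray) -> float:
    k = int(np.ceil(0.95 * sample.size))
    return float(np.sort(sample)[k - 1])


def mi_permutation_null(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null MI sample (labels_b shuffled) and its nearest-rank 95th percentile."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("labelings must be non-empty and equally long")
    rng = np.random.default_rng(seed)
    null = _null_mi_sample(a, b, n_perm, rng)
    return null, _nearest_rank_p95(null)


@dataclass(frozen=True)
class MIComparison:
    """Multi-scale MI between two dendrograms with permutation nulls."""

    name: str
    k_values: tuple[int, ...]
    mi: np.ndarray = field(repr=False)
    null_p95: np.ndarray = field(repr=False)
    n_perm: int
    seed: int

    #: values closer than this to the null 95th percentile count as ties,
    #: not exceedances (degenerate cuts make observed and null MI equal up
    #: to summation-order rounding)
    TIE_TOL = 1e-9

    @property
    def significant(self) -> np.ndarray:
        return self.mi > self.null_p95 + self.TIE_TOL

    def save_tsv(self, path: str | Path) -> None:
        labels = [str(k) for k in self.k_values]
        pd.DataFrame(self.mi, index=labels, columns=labels).to_csv(
            path, sep="\t", float_format="%.17g"
        )


def compare_dendrograms(
    d_a: Dendrogram,
    d_b: Dendrogram,
    k_range: range = range(2, 76),
    n_perm: int = 100,
    seed: int = 0,
    name: str = "",
) -> MIComparison:
    """Observed MI and permutation nulls for every cluster-size pair."""
    if d_a.n_leaves != d_b.n_leaves:
        raise ValueError("dendrograms must share a leaf set")
    ks = list(k_range)
    cuts_a = {k: d_a.cut(k) for k in ks}
    cuts_b = {k: d_b.cut(k) for k in ks}
    mi = np.empty((len(ks), len(ks)))
    p95 = np.empty_like(mi)
    rng = np.random.default_rng(seed)
    for i, ka in enumerate(ks):
        for j, kb in enumerate(ks):
            mi[i, j] = mutual_information(cuts_a[ka], cuts_b[kb])
            null = _null_mi_sample(cuts_a[ka], cuts_b[kb], n_perm, rng)
            p95[i, j] = _nearest_rank_p95(null)
    return MIComparison(
        name=name or f"{d_a.modality}:{d_a.group} vs {d_b.modality}:{d_b.group}",
        k_values=tuple(ks),
        mi=mi,
        null_p95=p95,
        n_perm=n_perm,
        seed=seed,
    )


def summarize_mi(comparison: MIComparison) -> tuple[float, float, int]:
    """(mean, SD, count) of MI over the significant cells.

    With no significant cell the mean and SD are NaN ("no significant
    overlap"), never an error.
    """
    mask = comparison.significant
    n_sig = int(mask.sum())
    if n_sig == 0:
        return float("nan"), float("nan"), 0
    vals = comparison.mi[mask]
    return float(vals.mean()), float(vals.std()), n_sig
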