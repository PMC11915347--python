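"""Symmetric connectivity-matrix container shared by every modality."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import from_upper_triangle, upper_triangle

MODALITIES = ("MC", "FC", "dMC", "dFC")

__all__ = ["ConnectivityMatrix", "MODALITIES"]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """An R x R symmetric edge-strength matrix tagged by modality and group.

    ``signed`` records whether negative edges are meaningful (signed MC/FC
    and both developmental-change modalities) or the matrix holds absolute
    strengths.  MC/FC matrices carry a unit diagonal; change matrices a
    zero diagonal.
    """

    modality: str
    group: str
    values: np.ndarray = field(repr=False)
    roi_names: tuple[str, ...]
    signed: bool = True
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        r = len(self.roi_names)
        if v.shape != (r, r):
            raise ValueError(f"values shape {v.shape} does not match {r} ROIs")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix contains non-finite values")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("connectivity matrix must be symmetric")
        if self.modality in ("MC", "FC"):
            if np.abs(v).max() > 1 + 1e-8:
                raise ValueError("correlation matrix has entries outside [-1, 1]")
            if np.abs(np.diag(v) - 1).max() > 1e-8:
                raise ValueError("MC/FC matrices must have a unit diagonal")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def upper(self) -> np.ndarray:
        """Edge vector in row-major upper-triangle order."""
        return upper_triangle(self.values)

    def absolute(self) -> "ConnectivityMatrix":
        v = np.abs(self.values)
        if self.modality in ("MC", "FC"):
            np.fill_diagonal(v, 1.0)
        return replace(self, values=v, signed=False)

    @classmethod
    def from_edges(
        cls,
        edges: np.ndarray,
        modality: str,
        group: str,
        roi_names: tuple[str, ...],
        diagonal: float = 0.0,
        signed: bool = True,
    ) -> "ConnectivityMatrix":
        return cls(modality, group, from_upper_triangle(edges, diagonal), tuple(roi_names), signed)

    # -- TSV round-trip (ROI names as header row/column) -----------------
    def save_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.roi_names, columns=self.roi_names)
        df.to_csv(path, sep="\t", float_format="%r".replace("r", ".17g"))

    @classmethod
    def load_tsv(
        cls, path: str | Path, modality: str, group: str, signed: bool = True
    ) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ROI names differ")
        return cls(modality, group, df.to_numpy(dtype=float), tuple(df.columns), signed)
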