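"""ROI atlas, edge indexing and connection-subset labeling.

The default parcellation covers 75 grey-matter regions: 31 DKT-style
cortical labels per hemisphere plus 13 subcortical parcels (medial
brainstem and bilateral thalamus, caudate, lenticular nucleus, amygdala,
hippocampus, cerebellum).  Every symmetric connectivity matrix in the
package is vectorized in a single fixed convention: the row-major upper
triangle with 0-based indices ``i < j``, which for 75 regions gives 2775
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROIAtlas",
    "EdgeSubsetLabeling",
    "InvalidAtlasError",
    "default_atlas",
    "load_atlas",
    "edge_index_pairs",
    "upper_triangle",
    "from_upper_triangle",
    "label_edges",
    "EDGE_CATEGORIES",
]

EDGE_CATEGORIES = (
    "cortico-subcortical",
    "subcortico-subcortical",
    "cc-intraH",
    "cc-interH-homo",
    "cc-interH-non-homo",
)

KNOWN_LOBES = frozenset(
    {"frontal", "parietal", "temporal", "occipital", "cingulate", "insular", "subcortical"}
)
KNOWN_TAGS = frozenset({"SM", "VIS", "thalamus"})


class InvalidAtlasError(ValueError):
    """Raised when an atlas violates its structural invariants."""


@dataclass(frozen=True)
class ROIAtlas:
    """Immutable region table driving all edge bookkeeping.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per ROI, indexed 0..R-1, with columns ``name``,
        ``hemisphere`` (L/R/medial), ``lobe``, ``is_cortical`` (bool),
        ``homotopic_partner`` (ROI id or -1) and ``system_tags``
        (frozenset of tags among SM/VIS/thalamus).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        r = self.n_rois
        return r * (r - 1) // 2

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def roi_id(self, name: str) -> int:
        hits = self.table.index[self.table["name"] == name]
        if len(hits) != 1:
            raise KeyError(f"ROI name {name!r} not found (or duplicated) in atlas")
        return int(hits[0])

    def is_cortical(self) -> np.ndarray:
        return self.table["is_cortical"].to_numpy(dtype=bool)

    def homotopic_partner(self) -> np.ndarray:
        return self.table["homotopic_partner"].to_numpy(dtype=int)

    def has_tag(self, tag: str) -> np.ndarray:
        return np.array([tag in tags for tags in self.table["system_tags"]], dtype=bool)

    def validate(self) -> None:
        t = self.table
        required = {"name", "hemisphere", "lobe", "is_cortical", "homotopic_partner", "system_tags"}
        missing = required - set(t.columns)
        if missing:
            raise InvalidAtlasError(f"atlas table missing columns: {sorted(missing)}")
        if list(t.index) != list(range(len(t))):
            raise InvalidAtlasError("atlas must be indexed contiguously from 0")
        if t["name"].duplicated().any():
            raise InvalidAtlasError("duplicate ROI names")
        bad_lobe = set(t["lobe"]) - KNOWN_LOBES
        if bad_lobe:
            raise InvalidAtlasError(f"unknown lobes: {sorted(bad_lobe)}")
        if not set(t["hemisphere"]) <= {"L", "R", "medial"}:
            raise InvalidAtlasError("hemisphere must be L, R or medial")
        partners = t["homotopic_partner"].to_numpy(dtype=int)
        for i, p in enumerate(partners):
            if p < 0:
                continue
            if p >= len(t) or partners[p] != i:
                raise InvalidAtlasError(f"homotopy map asymmetric at ROI {i} (partner {p})")
            hi, hp = t.loc[i, "hemisphere"], t.loc[p, "hemisphere"]
            if {hi, hp} != {"L", "R"}:
                raise InvalidAtlasError(f"homotopic partners must be L-R pairs (ROIs {i},{p})")
            base_i = t.loc[i, "name"].rsplit("-", 1)[0]
            base_p = t.loc[p, "name"].rsplit("-", 1)[0]
            if base_i != base_p:
                raise InvalidAtlasError(f"homotopic partners differ in base name: {base_i}, {base_p}")


def load_atlas(path: str | Path) -> ROIAtlas:
    """Read an atlas from CSV (see packaged ``dkt75_atlas.csv`` for the schema).

    ``system_tags`` is a semicolon-separated tag list; an empty
    ``homotopic_partner`` means the ROI has none.
    """
    df = pd.read_csv(path, dtype={"system_tags": "string"})
    df = df.sort_values("roi_id").reset_index(drop=True)
    if not (df["roi_id"] == np.arange(len(df))).all():
        raise InvalidAtlasError("roi_id column must enumerate 0..R-1")
    df["is_cortical"] = df["is_cortical"].astype(bool)
    df["homotopic_partner"] = (
        pd.to_numeric(df["homotopic_partner"], errors="coerce").fillna(-1).astype(int)
    )
    tags = []
    for raw in df["system_tags"].fillna(""):
        parsed = frozenset(x for x in str(raw).split(";") if x)
        bad = parsed - KNOWN_TAGS
        if bad:
            raise InvalidAtlasError(f"unknown system tags: {sorted(bad)}")
        tags.append(parsed)
    df["system_tags"] = tags
    return ROIAtlas(df.drop(columns=["roi_id"]))


def default_atlas() -> ROIAtlas:
    """The packaged 75-ROI atlas (31 DKT cortical labels per hemisphere
    plus brainstem and six bilateral subcortical structures)."""
    with resources.as_file(resources.files("gmconn.data") / "dkt75_atlas.csv") as p:
        atlas = load_atlas(p)
    if atlas.n_rois != 75:
        raise InvalidAtlasError("packaged atlas must have 75 ROIs")
    return atlas


# ---------------------------------------------------------------------------
# Edge indexing: row-major upper triangle, i < j, 0-based.
# ---------------------------------------------------------------------------

def edge_index_pairs(n_rois: int) -> np.ndarray:
    """(n_edges, 2) array of (i, j) with i < j in row-major upper-triangle order."""
    iu, ju = np.triu_indices(n_rois, k=1)
    return np.column_stack([iu, ju])


def upper_triangle(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Vectorize a symmetric matrix into edge order.

    Raises ``ValueError`` naming the worst entry if the matrix is
    asymmetric beyond ``tol``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    dev = np.abs(m - m.T)
    if dev.max() > tol:
        i, j = np.unravel_index(int(np.argmax(dev)), dev.shape)
        raise ValueError(
            f"matrix is asymmetric: max |M[{i},{j}] - M[{j},{i}]| = {dev[i, j]:.3e} > {tol:.0e}"
        )
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def from_upper_triangle(values: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`upper_triangle`; fills the diagonal with ``diagonal``."""
    v = np.asarray(values, dtype=float)
    n_edges = v.size
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} values do not form an upper triangle")
    m = np.full((r, r), diagonal, dtype=float)
    iu, ju = np.triu_indices(r, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return m


@dataclass(frozen=True)
class EdgeSubsetLabeling:
    """Per-edge categorical and boolean labels in upper-triangle order.

    ``category`` partitions the edges into the five mutually exclusive
    classes in :data:`EDGE_CATEGORIES`; the boolean flags mark
    thalamo-cortical edges and edges touching the primary sensorimotor
    (SM) or visual (VIS) systems.
    """

    category: np.ndarray
    thalamo_cortical: np.ndarray
    involves_sm: np.ndarray
    involves_vis: np.ndarray
    pairs: np.ndarray

    def mask(self, category: str) -> np.ndarray:
        if category not in EDGE_CATEGORIES:
            raise ValueError(f"unknown edge category {category!r}")
        return self.category == category

    def counts(self) -> dict[str, int]:
        return {c: int((self.category == c).sum()) for c in EDGE_CATEGORIES}

    def subset_masks(self) -> dict[str, np.ndarray]:
        """The named connection subsets used throughout the analysis.

        ``whole-brain`` is every edge; the stratified subsets exclude
        subcortico-subcortical edges except for their own entry.
        """
        return {
            "whole-brain": np.ones(len(self.category), dtype=bool),
            "cortico-subcortical": self.mask("cortico-subcortical"),
            "thalamo-cortical": self.thalamo_cortical.copy(),
            "cc-intraH": self.mask("cc-intraH"),
            "cc-interH-homo": self.mask("cc-interH-homo"),
            "cc-interH-non-homo": self.mask("cc-interH-non-homo"),
            "SM": self.involves_sm.copy(),
            "VIS": self.involves_vis.copy(),
        }


def label_edges(atlas: ROIAtlas) -> EdgeSubsetLabeling:
    """Assign each edge exactly one category plus system flags.

    Homotopic status requires both ROIs cortical and mutually partnered;
    the thalamo-cortical flag is a subset of cortico-subcortical.
    """
    atlas.validate()
    pairs = edge_index_pairs(atlas.n_rois)
    cortical = atlas.is_cortical()
    partner = atlas.homotopic_partner()
    hemi = atlas.table["hemisphere"].to_numpy()
    thal = atlas.has_tag("thalamus")
    sm = atlas.has_tag("SM")
    vis = atlas.has_tag("VIS")

    i, j = pairs[:, 0], pairs[:, 1]
    both_cortical = cortical[i] & cortical[j]
    neither_cortical = ~cortical[i] & ~cortical[j]
    category = np.empty(len(pairs), dtype=object)
    category[~both_cortical & ~neither_cortical] = "cortico-subcortical"
    category[neither_cortical] = "subcortico-subcortical"
    intra = both_cortical & (hemi[i] == hemi[j])
    category[intra] = "cc-intraH"
    inter = both_cortical & ~intra
    homo = inter & (partner[i] == j)
    category[inter] = "cc-interH-non-homo"
    category[homo] = "cc-interH-homo"

    thalamo_cortical = (thal[i] & cortical[j]) | (thal[j] & cortical[i])
    return EdgeSubsetLabeling(
        category=category.astype("U30"),
        thalamo_cortical=thalamo_cortical,
        involves_sm=sm[i] | sm[j],
        involves_vis=vis[i] | vis[j],
        pairs=pairs,
    )
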