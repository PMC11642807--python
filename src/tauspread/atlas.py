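"""Region atlas, connectome and cohort handling.

The pipeline operates on three tabular inputs that mirror how whole-brain
tau-mapping data are organised:

* a **region atlas** — one row per brain region with a stable id, an acronym,
  a hemisphere label (ipsi/contra relative to the injected hemisphere), a
  parent id encoding the anatomical hierarchy (Allen-atlas style), and a 3-D
  centroid in micrometres;
* a **connectome** — a directed, non-negative N x N weight matrix over an
  ordered region list.  Entry (i, j) is the projection strength from source
  region i to target region j (measured at the axon-terminal end).
  Anterograde spread uses the matrix as stored, retrograde spread its
  transpose; a Euclidean variant derives weights from centroid distances;
* a **cohort table** — long-format per-mouse, per-region measurements:
  AT8+ object density (``pathology``, objects/mm^2), optional tdT+ cell
  density (``tdt``, cells/mm^2), with genotype (WT | 5X) and treatment
  (Sal | PTZ) labels.

Everything is validated on load; dropped or filtered entities are reported
through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

HEMISPHERES = ("ipsi", "contra")
GENOTYPES = ("WT", "5X")
TREATMENTS = ("Sal", "PTZ")
TRACING_MODES = ("anterograde", "retrograde")
MODES = ("anterograde", "retrograde", "euclidean")

ATLAS_REQUIRED = ("region_id", "acronym", "hemisphere", "parent_id", "x", "y", "z")
COHORT_REQUIRED = ("mouse_id", "genotype", "treatment", "region_id", "pathology")


# ---------------------------------------------------------------------------
# Region atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionAtlas:
    """Validated region hierarchy with centroids.

    ``table`` is indexed by ``region_id`` and carries columns
    ``acronym, name, hemisphere, parent_id, x, y, z, level`` where ``level``
    is the depth in the hierarchy (roots are level 0).  Parent links form a
    forest: no cycles, and every non-root parent exists.
    """

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        missing = [c for c in ATLAS_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"atlas table missing columns: {missing}")
        df = df.copy()
        df["region_id"] = df["region_id"].astype(str)
        if df["region_id"].duplicated().any():
            dupes = sorted(df.loc[df["region_id"].duplicated(), "region_id"])
            raise ValidationError(f"duplicate region_id values: {dupes}")
        # empty / NaN parent -> root
        parent = df["parent_id"]
        parent = parent.where(~parent.isna(), None)
        parent = [None if p in (None, "", "nan", "None") else str(p) for p in parent]
        df["parent_id"] = parent
        if "name" not in df.columns:
            df["name"] = df["acronym"]

        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")

        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            bad = df.loc[~np.isfinite(coords).all(axis=1), "region_id"].tolist()
            raise ValidationError(f"non-finite centroids for regions: {bad}")
        df[["x", "y", "z"]] = coords

        ids = set(df["region_id"])
        for rid, pid in zip(df["region_id"], df["parent_id"]):
            if pid is not None and pid not in ids:
                raise ValidationError(f"region {rid!r} has unknown parent {pid!r}")

        # assign hierarchy levels by peeling from the roots; leftovers = cycle
        level: dict[str, int] = {}
        parent_of = dict(zip(df["region_id"], df["parent_id"]))
        frontier = [r for r, p in parent_of.items() if p is None]
        depth = 0
        children: dict[str, list[str]] = {}
        for r, p in parent_of.items():
            if p is not None:
                children.setdefault(p, []).append(r)
        while frontier:
            for r in frontier:
                level[r] = depth
            frontier = [c for r in frontier for c in children.get(r, [])]
            depth += 1
        unreached = sorted(ids - set(level))
        if unreached:
            raise ValidationError(
                f"cyclic parent links involving regions: {unreached}"
            )
        df["level"] = [level[r] for r in df["region_id"]]
        df = df.set_index("region_id", drop=False)
        df.index.name = None
        return cls(table=df)

    # -- accessors ---------------------------------------------------------

    @property
    def region_ids(self) -> list[str]:
        return list(self.table["region_id"])

    def centroids(self, regions: Sequence[str]) -> np.ndarray:
        """(len(regions), 3) centroid array in atlas units (micrometres)."""
        missing = [r for r in regions if r not in self.table.index]
        if missing:
            raise ValidationError(f"regions not in atlas: {missing}")
        return self.table.loc[list(regions), ["x", "y", "z"]].to_numpy(dtype=float)

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, pid in zip(self.table["region_id"], self.table["parent_id"]):
            if pid is not None:
                out.setdefault(pid, []).append(rid)
        return out

    def resolve_acronyms(
        self, acronyms: Iterable[str], within: Sequence[str] | None = None
    ) -> list[str]:
        """Map acronyms to region ids, optionally restricted to ``within``.

        Raises listing every acronym that resolves to no region.
        """
        pool = self.table
        if within is not None:
            pool = pool.loc[pool["region_id"].isin(set(within))]
        by_acr = pool.groupby("acronym")["region_id"].apply(list).to_dict()
        resolved: list[str] = []
        missing: list[str] = []
        for a in acronyms:
            hits = by_acr.get(a, [])
            if not hits:
                missing.append(a)
            resolved.extend(sorted(hits))
        if missing:
            raise ValidationError(f"acronyms not found in atlas: {missing}")
        return resolved


def load_atlas(path: str | Path) -> RegionAtlas:
    """Read a delimited atlas table (CSV, one row per region) and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"region_id": str, "parent_id": str})
    return RegionAtlas.from_frame(df)


def save_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    cols = ["region_id", "acronym", "name", "hemisphere", "parent_id", "x", "y", "z"]
    atlas.table[cols].to_csv(path, index=False, float_format="%.10g")


def aggregate_hierarchy(
    counts: Mapping[str, float], atlas: RegionAtlas
) -> dict[str, float]:
    """Sum detected-object counts up through the region hierarchy.

    Each region's total is its own count plus the totals of all of its
    descendants, mirroring how per-object detections are rolled up from
    subregions to parent structures.  Regions without a count contribute 0.
    """
    ids = set(atlas.table["region_id"])
    unknown = sorted(set(counts) - ids)
    if unknown:
        raise ValidationError(f"counts reference unknown regions: {unknown}")
    totals = {rid: float(counts.get(rid, 0.0)) for rid in ids}
    order = atlas.table.sort_values("level", ascending=False)
    for rid, pid in zip(order["region_id"], order["parent_id"]):
        if pid is not None:
            totals[pid] += totals[rid]
    return totals


# ---------------------------------------------------------------------------
# Connectome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connectome:
    """Directed non-negative weight matrix over an ordered region list.

    ``A[i, j]`` is the connection strength from source region i to target
    region j.  ``mode`` tags the interpretation: ``anterograde`` (as stored),
    ``retrograde`` (transpose view of a tracing matrix) or ``euclidean``
    (symmetric, distance-derived).
    """

    regions: tuple[str, ...]
    A: np.ndarray = field(repr=False)
    mode: str = "anterograde"

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        n = len(self.regions)
        if n < 2:
            raise ValidationError("connectome needs at least 2 regions")
        if A.shape != (n, n):
            raise ValidationError(f"weight matrix shape {A.shape} != ({n}, {n})")
        if np.isnan(A).any():
            raise ValidationError("NaN entries in weight matrix")
        if (A < 0).any():
            raise ValidationError("negative weights in connectivity matrix")
        if np.any(np.diag(A) != 0):
            raise ValidationError("connectome diagonal must be exactly 0")
        if self.mode not in MODES:
            raise ValidationError(f"unknown connectome mode {self.mode!r}")
        if len(set(self.regions)) != n:
            raise ValidationError("duplicate region ids in connectome")

    @property
    def n(self) -> int:
        return len(self.regions)

    def index_of(self, regions: Sequence[str]) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.regions)}
        missing = [r for r in regions if r not in pos]
        if missing:
            raise ValidationError(f"regions not in connectome: {missing}")
        return np.array([pos[r] for r in regions], dtype=int)


def directional_view(conn: Connectome, direction: str) -> Connectome:
    """Return the connectome oriented for anterograde or retrograde spread.

    The stored matrix has A[i, j] = projection strength i -> j; anterograde
    spread propagates along stored edges and retrograde spread along the
    transpose.  Applying the view twice returns the original matrix.
    """
    if conn.mode == "euclidean":
        raise ValidationError("direction is meaningless for a euclidean connectome")
    if direction not in TRACING_MODES:
        raise ValidationError(f"unknown direction {direction!r}")
    if direction == conn.mode:
        return conn
    return Connectome(regions=conn.regions, A=conn.A.T.copy(), mode=direction)


def oriented_views(
    A_stored: np.ndarray,
    regions: Sequence[str],
    direction_convention: str = "anterograde",
) -> dict[str, Connectome]:
    """Build both directional views from a raw tracing matrix.

    ``direction_convention`` states what the stored matrix measures:
    ``"anterograde"`` (default; A[i, j] = strength measured at the
    axon-terminal end of the i -> j projection) or ``"retrograde"`` to flip
    the assignment.  The ambiguity in how tract-tracing intensities map onto
    spread direction is thereby explicit rather than silently resolved.
    """
    if direction_convention not in TRACING_MODES:
        raise ValidationError(
            f"direction_convention must be one of {TRACING_MODES}"
        )
    base = Connectome(regions=tuple(regions), A=np.asarray(A_stored, dtype=float),
                      mode=direction_convention)
    other = "retrograde" if direction_convention == "anterograde" else "anterograde"
    return {direction_convention: base, other: directional_view(base, other)}


def build_euclidean_connectome(
    atlas: RegionAtlas,
    regions: Sequence[str],
    kernel: str = "inverse",
    length_scale: float | None = None,
) -> Connectome:
    """Distance-derived symmetric connectome over ``regions``.

    Off-diagonal weight is a decreasing function of the centroid distance
    d_ij: ``1/d`` (default) or ``exp(-d/length_scale)``.  Coincident
    centroids are rejected because the inverse kernel diverges.
    """
    regions = list(regions)
    if len(regions) < 2:
        raise ValidationError("need at least 2 regions")
    cents = atlas.centroids(regions)
    D = cdist(cents, cents)
    off = ~np.eye(len(regions), dtype=bool)
    if np.any(D[off] == 0):
        pairs = [(regions[i], regions[j]) for i, j in zip(*np.nonzero((D == 0) & off))]
        raise ValidationError(f"coincident centroids: {pairs[:5]}")
    if kernel == "inverse":
        W = np.zeros_like(D)
        W[off] = 1.0 / D[off]
    elif kernel == "exponential":
        if length_scale is None or length_scale <= 0:
            raise ValidationError("exponential kernel requires a positive length_scale")
        W = np.exp(-D / length_scale)
        np.fill_diagonal(W, 0.0)
    else:
        raise ValidationError(f"unknown kernel {kernel!r}")
    return Connectome(regions=tuple(regions), A=W, mode="euclidean")


def load_connectome(path: str | Path, mode: str = "anterograde") -> Connectome:
    """Read a square delimited weight matrix (header row/column of region ids)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise SchemaError("connectivity matrix row and column region ids differ")
    A = df.to_numpy(dtype=float)
    if np.isnan(A).any():
        raise ValidationError("NaN entries in connectivity matrix")
    return Connectome(regions=tuple(df.index), A=A, mode=mode)


def save_connectome(conn: Connectome, path: str | Path) -> None:
    pd.DataFrame(conn.A, index=conn.regions, columns=conn.regions).to_csv(
        path, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Validate a long-format cohort table and return a normalised copy."""
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    df = df.copy()
    if "tdt" not in df.columns:
        df["tdt"] = np.nan
    df["mouse_id"] = df["mouse_id"].astype(str)
    df["region_id"] = df["region_id"].astype(str)
    bad_g = set(df["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValidationError(f"unknown genotype labels: {sorted(bad_g)}")
    bad_t = set(df["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise ValidationError(f"unknown treatment labels: {sorted(bad_t)}")
    for col in ("pathology", "tdt"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError(f"negative values in {col!r}")
    dup = df.duplicated(subset=["mouse_id", "region_id"])
    if dup.any():
        pairs = df.loc[dup, ["mouse_id", "region_id"]].head(5).to_records(index=False)
        raise ValidationError(f"duplicate (mouse_id, region_id) rows, e.g. {list(pairs)}")
    if atlas is not None:
        unknown = sorted(set(df["region_id"]) - set(atlas.table["region_id"]))
        if unknown:
            raise ValidationError(f"cohort regions not in atlas: {unknown}")
    return df


def load_cohort(path: str | Path, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path), atlas=atlas)


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["mouse_id", "genotype", "treatment", "region_id", "pathology", "tdt"]
    df[cols].to_csv(path, index=False, float_format="%.10g")


def filter_regions(
    cohort: pd.DataFrame, min_per_group: int = 6
) -> tuple[pd.DataFrame, list[str]]:
    """Keep regions with at least ``min_per_group`` pathology samples per group.

    A region is retained iff **every** genotype x treatment group present in
    the cohort has at least ``min_per_group`` non-missing pathology values
    for it (default 6).  Returns the filtered cohort and the sorted list of
    excluded region ids for audit.
    """
    if min_per_group < 1:
        raise ValidationError("min_per_group must be >= 1")
    ok = cohort.dropna(subset=["pathology"])
    counts = (
        ok.groupby(["region_id", "genotype", "treatment"], observed=True)
        .size()
        .unstack(["genotype", "treatment"], fill_value=0)
    )
    counts = counts.reindex(sorted(set(cohort["region_id"])), fill_value=0)
    retained = counts.index[(counts >= min_per_group).all(axis=1)]
    excluded = sorted(set(cohort["region_id"]) - set(retained))
    if excluded:
        logger.info(
            "filter_regions: excluded %d region(s) below %d samples/group",
            len(excluded), min_per_group,
        )
    if len(retained) == 0:
        logger.warning("filter_regions: no region satisfies the filter")
    return cohort.loc[cohort["region_id"].isin(set(retained))].copy(), excluded


def regional_means(
    cohort: pd.DataFrame,
    regions: Sequence[str],
    column: str = "pathology",
) -> np.ndarray:
    """Per-region mean of ``column`` across mice, aligned to ``regions``.

    Regions with no non-missing value get NaN.
    """
    means = cohort.groupby("region_id", observed=True)[column].mean()
    return means.reindex(list(regions)).to_numpy(dtype=float)
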