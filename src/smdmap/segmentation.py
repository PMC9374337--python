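"""Cell detection, rotation onto the major axis, QC and region partitioning.

Cells are found as dense connected groups of points via a Voronoi
tessellation: points whose Voronoi polygon is small (high local density)
are kept and joined through shared Voronoi edges. Each detected cell is
rotated so its long axis lies along x (the leading eigenvector of the
position covariance), translated so the centroid sits at the origin, and
then split into left pole / center / right pole by the outer fraction of
its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, QhullError

NM_PER_UM = 1000.0

__all__ = [
    "VoronoiParams",
    "CellRecord",
    "RegionPartition",
    "ClusteringError",
    "cluster_cells",
    "rotate_to_major_axis",
    "measure_geometry",
    "qc_filter",
    "partition_regions",
]


class ClusteringError(RuntimeError):
    """Raised when the tessellation cannot be computed for a field of view."""


@dataclass(frozen=True)
class VoronoiParams:
    """Density-based clustering parameters.

    Points are kept when their Voronoi polygon area is below
    ``max_area_factor`` times the median finite polygon area of the field;
    clusters with fewer than ``min_cluster_size`` kept points are
    discarded.
    """

    max_area_factor: float = 2.0
    min_cluster_size: int = 500


def _point_columns(df: pd.DataFrame) -> tuple[str, str]:
    for xc, yc in (("x_nm", "y_nm"), ("origin_x_nm", "origin_y_nm")):
        if xc in df.columns and yc in df.columns:
            return xc, yc
    raise KeyError("expected x_nm/y_nm or origin_x_nm/origin_y_nm columns")


def _polygon_areas(vor: Voronoi) -> np.ndarray:
    areas = np.full(len(vor.points), np.inf)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def cluster_cells(
    points: pd.DataFrame,
    params: VoronoiParams = VoronoiParams(),
) -> list[pd.DataFrame]:
    """Detect cells as dense Voronoi-connected components of points.

    ``points`` may be a localization table (``x_nm``/``y_nm``) or a
    displacement table (``origin_x_nm``/``origin_y_nm``). Returns one
    DataFrame per detected cluster (rows of the input, order preserved),
    sorted by descending cluster size.
    """
    if points.empty:
        return []
    xc, yc = _point_columns(points)
    xy = points[[xc, yc]].to_numpy(float)
    if len(xy) < 4:
        raise ClusteringError("too few points for a Voronoi tessellation")
    try:
        vor = Voronoi(xy)
    except QhullError as err:  # degenerate (e.g. collinear) input
        raise ClusteringError(f"Voronoi tessellation failed: {err}") from err
    areas = _polygon_areas(vor)
    finite = areas[np.isfinite(areas)]
    if finite.size == 0:
        return []
    keep = areas < params.max_area_factor * np.median(finite)
    ridge = vor.ridge_points
    both = keep[ridge[:, 0]] & keep[ridge[:, 1]]
    kept_idx = np.flatnonzero(keep)
    remap = -np.ones(len(xy), dtype=int)
    remap[kept_idx] = np.arange(kept_idx.size)
    edges = remap[ridge[both]]
    n = kept_idx.size
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    clusters = []
    for lab in np.unique(labels):
        members = kept_idx[labels == lab]
        if members.size >= params.min_cluster_size:
            clusters.append(points.iloc[np.sort(members)])
    clusters.sort(key=len, reverse=True)
    return clusters


@dataclass
class CellRecord:
    """A detected cell in its own rotated frame of reference.

    ``displacements`` carries cell-local coordinates: origins rotated so
    the major axis is parallel to x and translated so the centroid is at
    the origin. ``length_um``/``width_um`` are the x/y extents of the
    displacement origins.
    """

    id: int
    displacements: pd.DataFrame
    rotation_angle: float
    length_um: float
    width_um: float
    qc_pass: bool = True
    qc_reason: str = ""
    axis_ambiguous: bool = False

    @property
    def n_displacements(self) -> int:
        return len(self.displacements)


def measure_geometry(points: pd.DataFrame) -> tuple[float, float]:
    """(length, width) in μm from the x/y extents of displacement origins."""
    if len(points) < 2:
        raise ValueError("geometry undefined for fewer than 2 points")
    xc, yc = _point_columns(points)
    length = float(points[xc].max() - points[xc].min()) / NM_PER_UM
    width = float(points[yc].max() - points[yc].min()) / NM_PER_UM
    return length, width


def rotate_to_major_axis(
    cluster: pd.DataFrame,
    cell_id: int = 0,
    eigen_rtol: float = 1e-3,
) -> CellRecord:
    """Rotate a cell's points so the covariance major axis lies along x.

    The rotation angle is the angle between the leading eigenvector of the
    origin-coordinate covariance matrix and the x axis, reported in
    (-pi/2, pi/2]. All positions (origins, and endpoints / displacement
    vectors when present) are rotated rigidly, so pairwise distances and
    displacement lengths are preserved. A cell whose covariance
    eigenvalues coincide (isotropic cloud) has no preferred axis; the
    angle is still returned but flagged ambiguous.
    """
    xc, yc = _point_columns(cluster)
    xy = cluster[[xc, yc]].to_numpy(float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points to orient a cell")
    centroid = xy.mean(axis=0)
    cov = np.cov((xy - centroid).T)
    if np.allclose(cov, 0):
        raise ValueError("cannot orient a degenerate (zero-extent) cluster")
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    angle = float(np.arctan2(major[1], major[0]))
    # direction of an axis is defined mod pi
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    ambiguous = bool(np.isclose(evals[0], evals[1], rtol=eigen_rtol))
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])

    local = cluster.copy()
    rotated = (xy - centroid) @ rot.T
    local[xc], local[yc] = rotated[:, 0], rotated[:, 1]
    if "end_x_nm" in local.columns and "end_y_nm" in local.columns:
        ends = cluster[["end_x_nm", "end_y_nm"]].to_numpy(float)
        ends = (ends - centroid) @ rot.T
        local["end_x_nm"], local["end_y_nm"] = ends[:, 0], ends[:, 1]
    if "dx_nm" in local.columns and "dy_nm" in local.columns:
        vec = cluster[["dx_nm", "dy_nm"]].to_numpy(float) @ rot.T
        local["dx_nm"], local["dy_nm"] = vec[:, 0], vec[:, 1]
    local = local.reset_index(drop=True)
    local.attrs.update(cluster.attrs)
    length, width = measure_geometry(local)
    return CellRecord(
        id=cell_id,
        displacements=local,
        rotation_angle=angle,
        length_um=length,
        width_um=width,
        axis_ambiguous=ambiguous,
    )


def qc_filter(
    cells: list[CellRecord],
    min_disp: int = 2000,
    max_disp: int = 20000,
    manual_flags: dict[int, str] | None = None,
) -> list[CellRecord]:
    """Keep cells whose displacement count lies in [min_disp, max_disp].

    Counts must be computed on already r-filtered displacements. Bounds
    are inclusive. ``manual_flags`` maps cell id to a caller-supplied
    exclusion reason (edge truncation, adjacent cells, division,
    aggregation) for criteria that require visual inspection; flagged
    cells fail QC regardless of their count. Rejected cells are returned
    nowhere but their ``qc_pass``/``qc_reason`` fields are updated in
    place.
    """
    manual_flags = manual_flags or {}
    kept = []
    for cell in cells:
        n = cell.n_displacements
        if cell.id in manual_flags:
            cell.qc_pass, cell.qc_reason = False, f"manual: {manual_flags[cell.id]}"
        elif n < min_disp:
            cell.qc_pass, cell.qc_reason = False, f"too few displacements ({n} < {min_disp})"
        elif n > max_disp:
            cell.qc_pass, cell.qc_reason = False, f"too many displacements ({n} > {max_disp})"
        else:
            cell.qc_pass, cell.qc_reason = True, ""
            kept.append(cell)
    return kept


@dataclass
class RegionPartition:
    """Disjoint left-pole / center / right-pole displacement subsets."""

    left_pole: pd.DataFrame
    center: pd.DataFrame
    right_pole: pd.DataFrame
    pole_fraction: float
    left_boundary_nm: float
    right_boundary_nm: float

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.left_pole), len(self.center), len(self.right_pole)


def partition_regions(cell: CellRecord, pole_fraction: float = 0.20) -> RegionPartition:
    """Split a rotated cell's displacements into poles and center by origin x.

    Each pole spans ``pole_fraction`` of the measured cell length from the
    respective extreme origin; ties at a boundary are assigned to the pole
    (fixed convention). For the reference cell geometry the default 0.20
    equals radius/length, i.e. the pole region covers the hemispherical
    cap.
    """
    if not 0 < pole_fraction < 0.5:
        raise ValueError("pole_fraction must lie in (0, 0.5): poles may not overlap")
    df = cell.displacements
    if df.empty:
        raise ValueError("cannot partition a cell with no displacements")
    xc, _ = _point_columns(df)
    x = df[xc].to_numpy(float)
    x_min, x_max = x.min(), x.max()
    length = x_max - x_min
    if length <= 0:
        raise ValueError("cell length must be positive")
    left_b = x_min + pole_fraction * length
    right_b = x_max - pole_fraction * length
    in_left = x <= left_b
    in_right = (x >= right_b) & ~in_left
    in_center = ~in_left & ~in_right
    return RegionPartition(
        left_pole=df.loc[in_left],
        center=df.loc[in_center],
        right_pole=df.loc[in_right],
        pole_fraction=pole_fraction,
        left_boundary_nm=float(left_b),
        right_boundary_nm=float(right_b),
    )
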