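"""Per-cell nuclear and chromosome-territory geometry.

The nucleus is proxied by the 3D convex hull of all decoded loci in a cell
(no membrane stain is assumed).  Radial positions are normalized by the
hull radius along the same direction: ``r = |p - c| / |q - c|`` where ``c``
is the hull's volume centroid and ``q`` the intersection of the ray from
``c`` through ``p`` with the hull surface, so 0 is the centre and 1 the
surface regardless of nuclear shape.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .io_core import log

RADIAL_CLIP_TOL = 0.05  # loci may sit marginally outside the hull due to noise


@dataclasses.dataclass
class CellGeometry:
    cell_id: str
    nuclear_volume: float | None    # µm^3; None below min_loci or degenerate
    centroid: np.ndarray | None
    n_loci_used: int
    degenerate: bool = False


def _hull_centroid(hull: ConvexHull) -> np.ndarray:
    """Volume centroid of a convex hull (not the mean of its points).

    The hull is decomposed into tetrahedra fanned from the vertex mean; the
    centroid is the volume-weighted mean of tetrahedron centroids.
    """
    ref = hull.points[hull.vertices].mean(axis=0)
    total_vol = 0.0
    weighted = np.zeros(3)
    for simplex in hull.simplices:
        a, b, c = hull.points[simplex]
        vol = abs(np.dot(a - ref, np.cross(b - ref, c - ref))) / 6.0
        weighted += vol * (a + b + c + ref) / 4.0
        total_vol += vol
    if total_vol == 0:
        return ref
    return weighted / total_vol


def nuclear_volume(cell_trace: pd.DataFrame, min_loci: int = 1250) -> CellGeometry:
    """Convex-hull nuclear volume of one cell's decoded loci.

    Returns volume ``None`` when fewer than ``min_loci`` loci were decoded
    (default 1250; the lenient alternative is 600) or when the point cloud is
    degenerate (coplanar / collinear).
    """
    cell_ids = cell_trace["cell_id"].unique()
    if len(cell_ids) != 1:
        raise ValueError("nuclear_volume expects the trace rows of a single cell")
    points = cell_trace[["x", "y", "z"]].to_numpy(float)
    n = len(points)
    if n < min_loci or n < 4:
        return CellGeometry(cell_ids[0], None, None, n)
    try:
        hull = ConvexHull(points)
    except QhullError:
        return CellGeometry(cell_ids[0], None, None, n, degenerate=True)
    return CellGeometry(cell_ids[0], float(hull.volume), _hull_centroid(hull), n)


def _ray_exit_distance(centroid: np.ndarray, directions: np.ndarray,
                       hull: ConvexHull) -> np.ndarray:
    """Distance from the centroid to the hull surface along each direction.

    Facet-by-facet parametric test: for outward facet normals ``n`` with
    offsets ``b`` (``n . x + b = 0``), the exit parameter is the smallest
    positive ``t`` with ``n . (c + t d) + b = 0`` among facets the ray leaves
    through; ties (ray through an edge) resolve to the nearest intersection.
    """
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    denom = directions @ normals.T                      # (n_pts, n_facets)
    numer = -(offsets + centroid @ normals.T)           # (n_facets,)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 1e-12, numer / denom, np.inf)
    return t.min(axis=1)


def radial_positions(cell_trace: pd.DataFrame,
                     clip_tol: float = RADIAL_CLIP_TOL) -> pd.DataFrame | None:
    """Normalized radial position in [0, 1] for every decoded locus of a cell.

    Returns None when the hull is degenerate.  Values beyond 1 (possible for
    hull vertices displaced by localization noise relative to the facet
    planes, numerically) are clipped to 1; more than 1% clipped beyond the
    tolerance triggers a warning.
    """
    points = cell_trace[["x", "y", "z"]].to_numpy(float)
    if len(points) < 4:
        return None
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    centroid = _hull_centroid(hull)
    delta = points - centroid
    dist = np.linalg.norm(delta, axis=1)
    safe = np.where(dist > 0, dist, 1.0)
    directions = delta / safe[:, None]
    exit_dist = _ray_exit_distance(centroid, directions, hull)
    with np.errstate(invalid="ignore"):
        r = np.where(dist > 0, dist / exit_dist, 0.0)
    n_clipped = int((r > 1 + clip_tol).sum())
    if n_clipped > 0.01 * len(r):
        log.warning("%d/%d radial positions clipped beyond tolerance",
                    n_clipped, len(r))
    out = cell_trace[["cell_id", "chrom", "locus_id", "homolog"]].copy()
    out["radial_position"] = np.clip(r, 0.0, 1.0)
    out["clipped"] = r > 1.0
    return out


def radial_profile(traces: pd.DataFrame, min_loci: int = 0) -> pd.DataFrame:
    """Radial positions for every cell in a trace table (cells below
    ``min_loci`` decoded loci or with degenerate hulls are skipped)."""
    frames = []
    for _, cell in traces.groupby("cell_id", sort=False):
        if len(cell) < max(min_loci, 4):
            continue
        prof = radial_positions(cell)
        if prof is not None:
            frames.append(prof)
    if not frames:
        return pd.DataFrame(columns=["cell_id", "chrom", "locus_id", "homolog",
                                     "radial_position", "clipped"])
    return pd.concat(frames, ignore_index=True)


def territory_radius_of_gyration(cell_trace: pd.DataFrame, chrom: str,
                                 homolog: int) -> float | None:
    """Radius of gyration (µm) of one chromosome homolog's decoded loci.

    Root-mean-square distance of the loci to their centroid; None with fewer
    than two loci.
    """
    sub = cell_trace[(cell_trace["chrom"] == chrom)
                     & (cell_trace["homolog"] == homolog)]
    points = sub[["x", "y", "z"]].to_numpy(float)
    if len(points) < 2:
        return None
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def territory_intermixing(cell_trace: pd.DataFrame, k: int = 10) -> pd.DataFrame | None:
    """Per-homolog chromosome-territory intermixing score in [0, 1].

    For each homolog, the mean over its loci of the fraction of the locus's
    ``k`` nearest neighbours (among all decoded loci of the cell) that belong
    to a *different* chromosome.  0 means fully segregated territories.
    Returns None when fewer than ``k + 1`` loci are decoded or only one
    chromosome is present.
    """
    if cell_trace["chrom"].nunique() < 2 or len(cell_trace) < k + 1:
        return None
    points = cell_trace[["x", "y", "z"]].to_numpy(float)
    chroms = cell_trace["chrom"].to_numpy()
    tree = cKDTree(points)
    _, neighbors = tree.query(points, k=k + 1)
    other = chroms[neighbors[:, 1:]] != chroms[:, None]
    frac_other = other.mean(axis=1)
    out = cell_trace[["cell_id", "chrom", "homolog"]].copy()
    out["frac_other"] = frac_other
    scores = (out.groupby(["cell_id", "chrom", "homolog"], sort=False)["frac_other"]
              .mean().reset_index(name="intermixing"))
    return scores


def cell_geometry_table(traces: pd.DataFrame, min_loci: int = 1250) -> pd.DataFrame:
    """Per-cell geometry summary across a trace table."""
    rows = []
    for cell_id, cell in traces.groupby("cell_id", sort=False):
        geom = nuclear_volume(cell, min_loci=min_loci)
        rows.append((cell_id, cell["cell_type"].iloc[0], cell["genotype"].iloc[0],
                     geom.nuclear_volume, geom.n_loci_used, geom.degenerate))
    return pd.DataFrame(rows, columns=["cell_id", "cell_type", "genotype",
                                       "nuclear_volume", "n_loci_used", "degenerate"])
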