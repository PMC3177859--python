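"""Brain-to-scalp distance computations.

Two distinct constructions are provided, matching how such distances are
used in practice:

* a whole-surface **normal-ray distance map**: from every vertex of the
  brain envelope, cast a ray along the outward normal and record the
  distance to the first scalp intersection;
* a **landmark nearest-point distance**: the exact 3D Euclidean minimum
  from a cortical landmark to the scalp mesh.

A slice-constrained variant restricts the nearest-point search to a single
image plane; it can only overestimate the 3D distance and exists to
quantify that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from . import _geometry
from .io_formats import Landmark
from .surfaces import SurfaceMesh

__all__ = [
    "DistanceMap",
    "LandmarkDistance",
    "ray_normal_distance_map",
    "nearest_scalp_distance",
    "slice_constrained_distance",
    "summarize_region",
]

#: Rays with no scalp hit within this range are flagged invalid and excluded
#: from summaries (ill-defined regions: ears, skull base, mesh holes).
DEFAULT_MAX_DISTANCE = 100.0


@dataclass
class DistanceMap:
    """Per-hull-vertex brain-to-scalp distances along outward normals."""

    hull: SurfaceMesh
    distance: np.ndarray       # mm, NaN where invalid
    valid: np.ndarray          # bool per hull vertex
    hit_point: np.ndarray      # (n, 3) world mm, NaN rows where invalid

    def __post_init__(self) -> None:
        d = self.distance[self.valid]
        if d.size and (np.any(d < 0) or not np.all(np.isfinite(d))):
            raise ValueError("valid distances must be finite and >= 0")


@dataclass
class LandmarkDistance:
    """Nearest-point distance from one landmark to the scalp surface."""

    name: str
    hemisphere: str
    distance: float
    closest_point: np.ndarray
    verified: bool = True  # False when the landmark fell outside the search range


def ray_normal_distance_map(hull: SurfaceMesh, scalp: SurfaceMesh,
                            max_distance: float = DEFAULT_MAX_DISTANCE,
                            use_index: bool = True) -> DistanceMap:
    """Distance from each hull vertex to the scalp along its outward normal.

    Ray origins are nudged slightly inward along the normal so a scalp
    triangle coincident with the hull vertex still registers as a hit at
    distance zero; the reported distance is measured from the true vertex.
    Vertices whose ray finds no scalp intersection within ``max_distance``,
    and vertices already flagged invalid on the hull (e.g. ventral
    truncation), stay invalid.
    """
    if hull.normals is None:
        raise ValueError("hull has no vertex normals; run vertex_normals first")
    if scalp.n_faces == 0:
        raise ValueError("empty scalp mesh")
    n = hull.n_vertices
    nudge = 1e-3
    origins = hull.vertices - nudge * hull.normals
    caster = _geometry.ray_first_hit if use_index else _geometry.ray_first_hit_bruteforce
    active = np.flatnonzero(hull.valid)
    t = np.full(n, np.inf)
    t[active], _ = caster(origins[active], hull.normals[active],
                          scalp.vertices, scalp.faces,
                          max_distance=max_distance + nudge)
    dist = np.maximum(t - nudge, 0.0)
    valid = hull.valid & np.isfinite(t) & (dist <= max_distance)
    distance = np.where(valid, dist, np.nan)
    hit = np.full((n, 3), np.nan)
    hit[valid] = origins[valid] + t[valid, None] * hull.normals[valid]
    return DistanceMap(hull=hull, distance=distance, valid=valid, hit_point=hit)


def nearest_scalp_distance(landmark: Landmark | np.ndarray, scalp: SurfaceMesh,
                           max_distance: float = DEFAULT_MAX_DISTANCE,
                           use_index: bool = True) -> LandmarkDistance:
    """Exact 3D Euclidean distance from a landmark to the scalp mesh.

    The minimum is taken over triangle interiors, edges and vertices (not
    vertices only), with ties broken to the lowest face index.  If the
    landmark lies further than ``max_distance`` outside the scalp bounding
    box the result is flagged unverified rather than silently returned.
    """
    if scalp.n_faces == 0:
        raise ValueError("empty scalp mesh")
    if isinstance(landmark, Landmark):
        name, hemi = landmark.name, landmark.hemisphere
        point = np.asarray(landmark.position, float)
    else:
        name, hemi = "point", "midline"
        point = np.asarray(landmark, float)
    if use_index:
        d, closest, _ = _geometry.nearest_point(point, scalp.vertices, scalp.faces)
    else:
        d, closest, _ = _geometry.nearest_point_bruteforce(point, scalp.vertices,
                                                           scalp.faces)
    lo = scalp.vertices.min(axis=0)
    hi = scalp.vertices.max(axis=0)
    outside = float(np.linalg.norm(np.maximum(0, np.maximum(lo - point, point - hi))))
    verified = outside <= max_distance
    return LandmarkDistance(name=name, hemisphere=hemi, distance=float(d),
                            closest_point=closest, verified=verified)


def slice_constrained_distance(landmark: Landmark | np.ndarray,
                               scalp: SurfaceMesh, plane: str) -> float:
    """Minimum distance from a landmark to the scalp contour in one plane.

    ``plane`` is ``"axial"`` (z = const), ``"coronal"`` (y) or
    ``"sagittal"`` (x), passing through the landmark.  Because the search
    is restricted to the in-plane contour, the result is always >= the 3D
    nearest-point distance, with equality only when the 3D closest point
    happens to lie in the plane.
    """
    normals = {"axial": (0.0, 0.0, 1.0), "coronal": (0.0, 1.0, 0.0),
               "sagittal": (1.0, 0.0, 0.0)}
    if plane not in normals:
        raise ValueError(f"unknown plane {plane!r}")
    point = (np.asarray(landmark.position, float) if isinstance(landmark, Landmark)
             else np.asarray(landmark, float))
    segments = trimesh.intersections.mesh_plane(
        scalp.as_trimesh(), plane_normal=normals[plane], plane_origin=point
    )
    if len(segments) == 0:
        raise ValueError(f"{plane} plane through {point} does not intersect the scalp")
    return float(_min_point_segment_distance(point, segments))


def _min_point_segment_distance(point: np.ndarray, segments: np.ndarray) -> float:
    a = segments[:, 0, :]
    b = segments[:, 1, :]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(proj - point, axis=1).min()


def summarize_region(dmap: DistanceMap,
                     region: np.ndarray | None = None) -> tuple[float, float, int]:
    """(mean, SD, n) of map distances over valid vertices in a region.

    ``region`` is a boolean vertex mask (default: all vertices).  Invalid
    vertices never contribute; SD is the population SD (ddof=0).
    """
    if region is None:
        region = np.ones(dmap.hull.n_vertices, dtype=bool)
    region = np.asarray(region, dtype=bool)
    sel = region & dmap.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no valid vertices in region")
    d = dmap.distance[sel]
    return float(d.mean()), float(d.std(ddof=0)), n
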