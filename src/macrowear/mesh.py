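"""Geometry substrate: mesh I/O, surface areas, best-fit planes, plane slicing.

Crowns are triangulated surfaces (`trimesh.Trimesh`); all lengths are in mm.
The functions here are deliberately small and orientation-agnostic — every
downstream measurement (facet areas, inclinations, occlusal relief) reduces
to areas, least-squares planes and exact plane clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh

log = logging.getLogger(__name__)

#: triangles smaller than this (mm^2) are dropped at load: they destabilise
#: plane fits without contributing measurable area
DEGENERATE_AREA_TOL = 1e-12

_SUPPORTED_FORMATS = {"ply", "obj", "stl"}


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or is structurally invalid."""


class RankDeficiencyError(ValueError):
    """Raised when a plane fit is attempted on collinear or duplicate points."""


@dataclass(frozen=True)
class Plane:
    """An oriented plane ``normal . x = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise ValueError(f"plane normal must be unit length, got |n|={norm!r}")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed height of ``points`` above the plane (positive on the normal side)."""
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)

    @property
    def origin(self) -> np.ndarray:
        """An arbitrary point on the plane (foot of the normal from the origin)."""
        return self.normal * self.offset


@dataclass
class CrossSection:
    """Closed intersection contour(s) of a mesh with a plane.

    ``loops`` are ordered 2D polylines in plane coordinates; ``area`` is the
    enclosed area with holes subtracted (shoelace per loop, nested loops
    signed by containment — shapely handles the bookkeeping).
    """

    loops: list = field(default_factory=list)
    area: float = 0.0


def read_mesh(path, fmt: str | None = None) -> trimesh.Trimesh:
    """Load a triangulated surface from PLY, OBJ or (ASCII/binary) STL.

    Degenerate triangles (area < 1e-12 mm^2) are removed with a warning.
    STL carries no connectivity, so exactly coincident vertices are merged.
    Per-face integer attributes present in PLY are preserved on
    ``mesh.metadata['_ply_raw']`` / ``mesh.face_attributes`` by trimesh.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {sorted(_SUPPORTED_FORMATS)}")
    try:
        loaded = trimesh.load(path, file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle faces found (empty mesh)")
    mesh = loaded
    if fmt == "stl":
        mesh.merge_vertices(merge_tex=True, merge_norm=True)
    if np.any(mesh.faces >= len(mesh.vertices)) or np.any(mesh.faces < 0):
        raise MeshFormatError(f"{path}: face references vertex index out of range")
    areas = mesh.area_faces
    bad = areas < DEGENERATE_AREA_TOL
    if bad.any():
        log.warning("%s: dropping %d degenerate faces (area < %g mm^2)", path, int(bad.sum()), DEGENERATE_AREA_TOL)
        mesh.update_faces(~bad)
        if len(mesh.faces) == 0:
            raise MeshFormatError(f"{path}: all faces degenerate")
    return mesh


def surface_area(mesh: trimesh.Trimesh, face_subset=None) -> float:
    """Total triangle area (mm^2), optionally over a face-index subset."""
    areas = mesh.area_faces
    if face_subset is None:
        return float(areas.sum())
    face_subset = np.asarray(face_subset)
    if face_subset.size == 0:
        return 0.0
    if face_subset.dtype == bool:
        if face_subset.shape[0] != len(areas):
            raise IndexError("boolean face mask length does not match face count")
        return float(areas[face_subset].sum())
    if face_subset.min() < 0 or face_subset.max() >= len(areas):
        raise IndexError("face subset index out of range")
    return float(areas[face_subset].sum())


def fit_plane(points: np.ndarray, weights=None, normal_hint=None) -> Plane:
    """Total-least-squares plane through ``points``.

    Minimises the weighted sum of squared *orthogonal* distances (rotation
    invariant, unlike a vertical-distance fit): the normal is the smallest
    principal axis of the weighted covariance, computed as the last right
    singular vector of the sqrt-weight-scaled centred points. The normal
    sign follows ``normal_hint`` when given, else the first nonzero
    component is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise RankDeficiencyError("plane fit needs at least 3 three-dimensional points")
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pts),) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, one per point, not all zero")
    w = w / w.sum()
    centroid = w @ pts
    d = (pts - centroid) * np.sqrt(w)[:, None]
    s, vt = np.linalg.svd(d, full_matrices=False)[1:]
    scale = max(s[0], np.finfo(float).tiny)
    if s[1] / scale < 1e-7:
        raise RankDeficiencyError("points are collinear or coincident; plane is not defined")
    normal = vt[-1]
    if normal_hint is not None:
        if np.dot(normal, np.asarray(normal_hint, dtype=float)) < 0:
            normal = -normal
    else:
        nz = np.nonzero(np.abs(normal) > 1e-14)[0]
        if nz.size and normal[nz[0]] < 0:
            normal = -normal
    return Plane(normal, float(normal @ centroid))


def _clip_fractions(h: np.ndarray) -> np.ndarray:
    """Fraction of each triangle's area on the nonnegative side of a plane.

    ``h`` is (n_faces, 3) signed vertex heights. Clipping a triangle by a
    line through two edges leaves a similar-triangle area ratio, which gives
    a closed form per sign pattern; vertices exactly on the plane count as
    above. Exact up to floating arithmetic — no whole-triangle heuristics.
    """
    h = np.asarray(h, dtype=float)
    above = h >= 0.0
    n_above = above.sum(axis=1)
    frac = np.zeros(len(h))
    frac[n_above == 3] = 1.0

    one = n_above == 1
    if one.any():
        rows = np.where(one)[0]
        ia = above[rows].argmax(axis=1)
        ha = h[rows, ia]
        hb = h[rows, (ia + 1) % 3]
        hc = h[rows, (ia + 2) % 3]
        denom = (ha - hb) * (ha - hc)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, ha * ha / denom, 1.0)
        frac[rows] = np.clip(f, 0.0, 1.0)

    two = n_above == 2
    if two.any():
        rows = np.where(two)[0]
        ib = (~above[rows]).argmax(axis=1)  # the single below vertex
        hb = h[rows, ib]
        ha = h[rows, (ib + 1) % 3]
        hc = h[rows, (ib + 2) % 3]
        denom = (hb - ha) * (hb - hc)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, 1.0 - hb * hb / denom, 1.0)
        frac[rows] = np.clip(f, 0.0, 1.0)
    return frac


def face_areas_above_plane(mesh: trimesh.Trimesh, plane: Plane) -> np.ndarray:
    """Per-face area (mm^2) lying on the nonnegative side of ``plane``.

    Keeps face identity through the clip, so attribute channels (facet label,
    tissue) can be tallied over the occlusal region. Sums to the area of the
    clipped above-part.
    """
    heights = plane.signed_distance(mesh.vertices)
    return mesh.area_faces * _clip_fractions(heights[mesh.faces])


def slice_above_plane(mesh: trimesh.Trimesh, plane: Plane):
    """Clip ``mesh`` at ``plane``; return (above-part mesh, CrossSection).

    Straddling triangles are cut exactly at the plane. The cross-section is
    the closed intersection contour with its enclosed planar area (holes
    subtracted). A plane entirely above the mesh yields an empty above-part
    and a zero-area section rather than an error.
    """
    heights = plane.signed_distance(mesh.vertices)
    if (heights < 0).all():
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int), process=False), CrossSection()
    above = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.origin)
    section = cross_section(mesh, plane)
    return above, section


def _plane_basis(normal: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def _section_area(mesh: trimesh.Trimesh, plane: Plane) -> float:
    """Area enclosed by the plane-intersection contour, holes subtracted.

    Computed as the line integral ½ ∮ (x dy − y dx) over the intersection
    segments of straddling triangles, each oriented by the surface winding
    (tangent = face normal × plane normal). Requires a consistently wound
    mesh but no contour chaining, so it is robust where intersection points
    crowd together. Outer loops and nested holes acquire opposite signs
    automatically.
    """
    h = plane.signed_distance(mesh.vertices)
    tri_h = h[mesh.faces]
    above = tri_h >= 0.0
    n_above = above.sum(axis=1)
    rows = np.where((n_above == 1) | (n_above == 2))[0]
    if rows.size == 0:
        return 0.0
    u, v = _plane_basis(plane.normal)
    basis = np.column_stack([u, v])
    total = 0.0
    tri_v = mesh.vertices[mesh.faces[rows]]
    tri_hh = tri_h[rows]
    normals = mesh.face_normals[rows]
    for verts, hh, fn in zip(tri_v, tri_hh, normals):
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if (hh[i] >= 0.0) != (hh[j] >= 0.0):
                t = hh[i] / (hh[i] - hh[j])
                pts.append(verts[i] + t * (verts[j] - verts[i]))
        if len(pts) != 2:
            continue
        a2, b2 = pts[0] @ basis, pts[1] @ basis
        tangent = np.cross(fn, plane.normal) @ basis
        if np.dot(b2 - a2, tangent) < 0:
            a2, b2 = b2, a2
        total += 0.5 * (a2[0] * b2[1] - a2[1] * b2[0])
    return abs(total)


def cross_section(mesh: trimesh.Trimesh, plane: Plane) -> CrossSection:
    """Closed intersection contour(s) of ``mesh`` with ``plane`` and their area.

    The enclosed area comes from the chaining-free line integral
    (:func:`_section_area`); the discrete loops are reported for inspection
    when trimesh can chain them.
    """
    area = _section_area(mesh, plane)
    loops = []
    path3d = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if path3d is not None and len(path3d.entities) > 0:
        u, v = _plane_basis(plane.normal)
        loops = [np.asarray(d) @ np.column_stack([u, v]) for d in path3d.discrete]
    return CrossSection(loops=loops, area=area)


def projected_outline_area(mesh: trimesh.Trimesh, plane: Plane) -> float:
    """Area of the planar footprint of ``mesh`` projected onto ``plane``.

    Union of the projected triangles (shapely); used as the degenerate-case
    reading of the slice footprint when the surface touches the plane
    without crossing it, where the intersection contour is empty.
    """
    if len(mesh.faces) == 0:
        return 0.0
    u, v = _plane_basis(plane.normal)
    pts2 = mesh.vertices @ np.column_stack([u, v])
    tris = pts2[mesh.faces]
    polys = [shapely.Polygon(t) for t in tris]
    merged = shapely.union_all([p for p in polys if p.is_valid and p.area > 0])
    return float(merged.area)


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Dihedral angle between two planes in degrees, folded to [0, 90]."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
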