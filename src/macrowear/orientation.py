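"""Cervical reference frame and occlusal plane.

Every measurement is defined against two parallel planes: the *cervical
plane*, a total-least-squares fit through points sampled on the cervical
line (the enamel–root junction), and the *occlusal plane*, the plane
parallel to it through the central fossa (the deepest point of the occlusal
basin). Orientation is the rigid motion that maps the cervical plane onto
height zero with the crown pointing to +z; the cervical-plane normal is the
height axis throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, Delaunay

from .mesh import Plane, fit_plane


#: the occlusal plane sits a sliver below the central fossa, so the deepest
#: point lies strictly above it: a plane exactly through the fossa vertex
#: makes the slice contour degenerate where many triangles meet. The offset
#: scales with the fossa height so measurements stay scale invariant.
OCCLUSAL_PLANE_REL_EPS = 1e-6


def occlusal_offset(fossa_height: float) -> float:
    return float(fossa_height) - OCCLUSAL_PLANE_REL_EPS * max(abs(float(fossa_height)), 1e-3)


class OrientationAmbiguityError(ValueError):
    """Crown side of the cervical plane cannot be decided from the mesh."""


class CentralFossaError(ValueError):
    """Automatic fossa detection failed; a manual point is required."""


@dataclass
class ReferenceFrame:
    """Rigid map from scan coordinates into the cervical frame.

    After applying ``transform`` (4x4 homogeneous), the cervical plane is
    z = 0 and the crown occupies z > 0. ``fossa`` (set once located) is the
    central fossa in *oriented* coordinates; the occlusal plane is then
    z = fossa[2].
    """

    cervical_plane: Plane
    transform: np.ndarray
    fossa: np.ndarray | None = None

    @property
    def height_axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def occlusal_plane(self) -> Plane:
        if self.fossa is None:
            raise CentralFossaError("central fossa not located; call find_central_fossa first")
        return Plane(self.height_axis, occlusal_offset(self.fossa[2]))


def fit_cervical_plane(cervical_points: np.ndarray, mesh: trimesh.Trimesh | None = None) -> Plane:
    """Least-squares plane through the cervical line, normal toward the crown.

    ``cervical_points`` may be an ordered polyline or an unordered sample;
    the fit ignores ordering. When ``mesh`` is given, the normal is flipped
    so that the majority of mesh vertices lie on the positive side (the
    crown side); an exact tie raises, since the convention is then undefined.
    """
    plane = fit_plane(cervical_points)
    if mesh is not None:
        side = plane.signed_distance(mesh.vertices)
        n_pos = int((side > 0).sum())
        n_neg = int((side < 0).sum())
        if n_pos == n_neg:
            raise OrientationAmbiguityError(
                "exactly half the mesh vertices lie on each side of the cervical plane")
        if n_neg > n_pos:
            plane = plane.flipped()
    return plane


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """3x3 rotation carrying ``normal`` onto +z (Rodrigues; stable antipodal case)."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(n, z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def orient_mesh(mesh: trimesh.Trimesh, cervical_plane: Plane):
    """Rigidly move ``mesh`` so the cervical plane becomes z = 0, crown at +z.

    Returns ``(oriented_copy, ReferenceFrame)``. Pure isometry: every area,
    angle and ratio measured downstream is unchanged by the map.
    """
    rot = _rotation_to_z(cervical_plane.normal)
    transform = np.eye(4)
    transform[:3, :3] = rot
    transform[:3, 3] = -rot @ (cervical_plane.normal * cervical_plane.offset)
    oriented = mesh.copy()
    oriented.apply_transform(transform)
    return oriented, ReferenceFrame(cervical_plane=cervical_plane, transform=transform)


def _local_height_maxima(mesh: trimesh.Trimesh, threshold: float) -> np.ndarray:
    """Vertex indices that are height maxima over their 1-ring, above threshold."""
    z = mesh.vertices[:, 2]
    neighbors = mesh.vertex_neighbors
    out = []
    for i in np.where(z >= threshold)[0]:
        nbrs = neighbors[i]
        if len(nbrs) and z[i] >= z[list(nbrs)].max():
            out.append(i)
    return np.asarray(out, dtype=int)


def find_central_fossa(oriented_mesh: trimesh.Trimesh, manual_point=None,
                       apex_fraction: float = 0.75) -> np.ndarray:
    """Locate the central fossa of an oriented crown (crown at +z).

    A supplied ``manual_point`` is returned verbatim (the measurement
    workflows of record located the fossa by eye, so the override is
    first-class). Otherwise: cusp apices are the local height maxima above
    ``apex_fraction`` of the maximum height; the fossa is the lowest vertex
    whose xy-projection lies strictly inside the 2D convex hull of the apex
    projections. A crown with no basin (monotone dome) raises
    :class:`CentralFossaError` asking for the manual point.
    """
    if manual_point is not None:
        return np.asarray(manual_point, dtype=float)
    z = oriented_mesh.vertices[:, 2]
    apices = _local_height_maxima(oriented_mesh, apex_fraction * z.max())
    if len(apices) >= 3:
        pts2d = oriented_mesh.vertices[apices, :2]
        try:
            hull = ConvexHull(pts2d)
        except Exception:
            raise CentralFossaError(
                "cusp apices are collinear; supply the central fossa manually") from None
        tri = Delaunay(pts2d[hull.vertices])
        inside = tri.find_simplex(oriented_mesh.vertices[:, :2]) >= 0
        inside[apices] = False
        if inside.any():
            candidates = np.where(inside)[0]
            return np.asarray(oriented_mesh.vertices[candidates[z[candidates].argmin()]], dtype=float)
    raise CentralFossaError(
        "no occlusal basin found inside the cusp-apex hull; supply the central fossa manually")


def establish_frame(mesh: trimesh.Trimesh, cervical_points: np.ndarray,
                    manual_fossa=None):
    """Full orientation step: cervical fit, rigid move, fossa, occlusal plane.

    ``manual_fossa`` is interpreted in the *original* (scan) coordinates.
    Returns ``(oriented_mesh, frame)`` with ``frame.fossa`` set.
    """
    plane = fit_cervical_plane(cervical_points, mesh=mesh)
    oriented, frame = orient_mesh(mesh, plane)
    if manual_fossa is not None:
        p = np.asarray(manual_fossa, dtype=float)
        manual_oriented = (frame.transform[:3, :3] @ p) + frame.transform[:3, 3]
        frame.fossa = find_central_fossa(oriented, manual_point=manual_oriented)
    else:
        frame.fossa = find_central_fossa(oriented)
    return oriented, frame
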