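"""Topographic indices of the occlusal surface: OR, PDE, PEW.

* OR (occlusal relief index) — 3D area of the crown above the occlusal
  plane divided by the 2D area enclosed by the slice contour. Sharp,
  sculpted crowns have high OR; a flat surface has OR = 1.
* PDE (percentage of dentine exposure) — dentine area within the occlusal
  region over the 3D occlusal area, x100.
* PEW (percentage of enamel wear) — total wear area (TWA) over the 3D
  occlusal area, x100.

The occlusal plane is parallel to the cervical plane through the central
fossa (see :mod:`macrowear.orientation`). The "2D area" is the area enclosed
by the occlusal-plane cross-section contour — the slice footprint — not the
sum of projected triangle areas; the two differ on overhangs and only the
footprint keeps OR >= 1 for height-field crowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .facets import FacetMap, WearAreaProfile
from .mesh import (Plane, cross_section, face_areas_above_plane,
                   projected_outline_area)

log = logging.getLogger(__name__)


class UndefinedReliefError(ValueError):
    """Empty above-part or zero-area slice: OR is not defined."""


class WearAreaOverflowError(ValueError):
    """TWA exceeds the occlusal 3D area: labels inconsistent with the slice."""


@dataclass
class TopographicMetrics:
    OR: float
    PDE: float
    PEW: float
    occlusal_3d_area: float
    occlusal_2d_area: float


def occlusal_relief(oriented_mesh: trimesh.Trimesh, occlusal_plane: Plane):
    """Occlusal relief index.

    Returns ``(OR, occlusal_3d_area, occlusal_2d_area)``. The 3D area sums
    the exactly clipped triangle parts above the plane; the 2D area is the
    enclosed area of the slice contour.
    """
    area3d = float(face_areas_above_plane(oriented_mesh, occlusal_plane).sum())
    section = cross_section(oriented_mesh, occlusal_plane)
    area2d = section.area
    if area3d > 0.0 and area2d <= 0.0:
        # surface touches the plane without crossing it (e.g. a flat region
        # lying in the plane's positive closure): the footprint of the
        # above faces stands in for the empty intersection contour
        fracs = face_areas_above_plane(oriented_mesh, occlusal_plane) / oriented_mesh.area_faces
        above = oriented_mesh.submesh([np.where(fracs > 0.5)[0]], append=True)
        area2d = projected_outline_area(above, occlusal_plane)
    if area3d <= 0.0 or area2d <= 0.0:
        raise UndefinedReliefError(
            f"occlusal relief undefined: 3D area {area3d:.3g}, 2D area {area2d:.3g}")
    return area3d / area2d, area3d, area2d


def percent_dentine_exposure(mesh: trimesh.Trimesh, facet_map: FacetMap,
                             occlusal_3d_area: float, occlusal_plane: Plane | None = None) -> float:
    """PDE: dentine area over the 3D occlusal area, x100.

    Only dentine above the occlusal plane counts; dentine below (e.g.
    cervical abrasion) is excluded with a warning, since the normaliser is
    the occlusal area.
    """
    if occlusal_3d_area <= 0:
        raise ValueError("occlusal 3D area must be positive")
    mask = facet_map.dentine_mask
    if occlusal_plane is None:
        dent = float(mesh.area_faces[mask].sum())
    else:
        above = face_areas_above_plane(mesh, occlusal_plane)
        dent = float(above[mask].sum())
        dropped = float(mesh.area_faces[mask].sum()) - dent
        if dropped > 1e-9:
            log.warning("excluding %.4g mm^2 of dentine below the occlusal plane", dropped)
    return 100.0 * dent / occlusal_3d_area


def percent_enamel_wear(wear_profile: WearAreaProfile, occlusal_3d_area: float) -> float:
    """PEW: total wear area over the 3D occlusal area, x100."""
    if occlusal_3d_area <= 0:
        raise ValueError("occlusal 3D area must be positive")
    pew = 100.0 * wear_profile.twa / occlusal_3d_area
    if pew > 100.0 + 1e-6:
        raise WearAreaOverflowError(
            f"TWA {wear_profile.twa:.4g} mm^2 exceeds occlusal 3D area "
            f"{occlusal_3d_area:.4g} mm^2 (PEW = {pew:.2f}%)")
    return pew


def topographic_metrics(oriented_mesh: trimesh.Trimesh, facet_map: FacetMap,
                        occlusal_plane: Plane, wear_profile: WearAreaProfile | None = None) -> TopographicMetrics:
    """OR, PDE and PEW for one oriented, labelled crown.

    ``wear_profile`` may be passed to avoid recomputation; PEW is 0 for an
    unworn crown (no profile and no worn faces).
    """
    orr, a3d, a2d = occlusal_relief(oriented_mesh, occlusal_plane)
    pde = percent_dentine_exposure(oriented_mesh, facet_map, a3d, occlusal_plane)
    pew = 0.0 if wear_profile is None else percent_enamel_wear(wear_profile, a3d)
    return TopographicMetrics(OR=orr, PDE=pde, PEW=pew, occlusal_3d_area=a3d, occlusal_2d_area=a2d)
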