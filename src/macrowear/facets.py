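"""Occlusal fingerprint analysis: wear-facet areas and inclinations.

Wear facets on lower molars are numbered after the Maier–Schneck scheme
(1–13 plus the accessory facets 1.1, 2.1, 5.1, 8.1, 10.1) and grouped by
chewing-stroke phase: buccal phase I (1, 1.1, 2, 2.1, 3, 4), lingual
phase I (5, 5.1, 6, 7, 8, 8.1) and phase II (9, 10, 10.1, 11, 12, 13).
Tip crush areas — flattened cusp apices worn during puncture-crushing —
are merged into phase II for the *area* analysis but kept separate for the
*inclination* analysis, because their angles differ systematically.

Relative areas divide each facet's absolute area by the total wear area
(TWA, the sum over all facets including tip crush), removing tooth size.
Inclination is the angle between a facet's best-fit plane and the cervical
plane, folded to [0, 90] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .mesh import fit_plane

BUCCAL_PI = "BUCCAL_PI"
LINGUAL_PI = "LINGUAL_PI"
PHASE_II = "PHASE_II"
TIP_CRUSH = "TIP_CRUSH"
UNWORN = "UNWORN"
NONE = "NONE"

PHASES = (BUCCAL_PI, LINGUAL_PI, PHASE_II)

#: closed facet-label vocabulary
FACET_LABELS = ("1", "1.1", "2", "2.1", "3", "4",
                "5", "5.1", "6", "7", "8", "8.1",
                "9", "10", "10.1", "11", "12", "13",
                TIP_CRUSH, UNWORN)

#: facet label -> phase group
PHASE_OF = {
    **{f: BUCCAL_PI for f in ("1", "1.1", "2", "2.1", "3", "4")},
    **{f: LINGUAL_PI for f in ("5", "5.1", "6", "7", "8", "8.1")},
    **{f: PHASE_II for f in ("9", "10", "10.1", "11", "12", "13")},
    TIP_CRUSH: TIP_CRUSH,
    UNWORN: NONE,
}

#: integer codebook for per-face PLY channels (0 reserved for unworn)
FACET_CODEBOOK = {label: i for i, label in enumerate([UNWORN] + [f for f in FACET_LABELS if f != UNWORN])}
FACET_FROM_CODE = {v: k for k, v in FACET_CODEBOOK.items()}

ENAMEL, DENTINE = "enamel", "dentine"


class UnwornSpecimenError(ValueError):
    """Every face is unworn: TWA = 0 and relative areas are undefined."""


class MissingFacetError(KeyError):
    """The requested facet has no faces in the map."""


@dataclass
class FacetMap:
    """Per-face facet label plus per-face tissue flag (two independent channels).

    A dentine-flagged face may carry any facet label: dentine exposed inside
    a wear facet contributes both to that facet's area and to the dentine
    tally.
    """

    facet: np.ndarray  # array of str labels, one per face
    tissue: np.ndarray  # 'enamel' | 'dentine', one per face

    def __post_init__(self) -> None:
        self.facet = np.asarray(self.facet, dtype=object)
        self.tissue = np.asarray(self.tissue, dtype=object)
        if self.facet.shape != self.tissue.shape or self.facet.ndim != 1:
            raise ValueError("facet and tissue channels must be 1-D and aligned")
        bad = set(self.facet) - set(FACET_LABELS)
        if bad:
            raise ValueError(f"unknown facet labels {sorted(bad)}; allowed: {FACET_LABELS}")
        badt = set(self.tissue) - {ENAMEL, DENTINE}
        if badt:
            raise ValueError(f"unknown tissue flags {sorted(badt)}")

    def __len__(self) -> int:
        return len(self.facet)

    @classmethod
    def unworn(cls, n_faces: int) -> "FacetMap":
        return cls(np.full(n_faces, UNWORN, dtype=object), np.full(n_faces, ENAMEL, dtype=object))

    def faces_of(self, facet: str) -> np.ndarray:
        return np.where(self.facet == facet)[0]

    @property
    def dentine_mask(self) -> np.ndarray:
        return self.tissue == DENTINE

    @classmethod
    def from_csv(cls, path, n_faces: int | None = None) -> "FacetMap":
        """Read a sidecar CSV with columns face_index, facet_id, tissue."""
        df = pd.read_csv(path, dtype={"facet_id": str, "tissue": str})
        required = {"face_index", "facet_id", "tissue"}
        if not required.issubset(df.columns):
            raise ValueError(f"facet sidecar must have columns {sorted(required)}")
        n = n_faces if n_faces is not None else int(df["face_index"].max()) + 1
        fm = cls.unworn(n)
        idx = df["face_index"].to_numpy(int)
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("face_index out of range for the mesh")
        fm.facet[idx] = df["facet_id"].to_numpy(object)
        fm.tissue[idx] = df["tissue"].to_numpy(object)
        return cls(fm.facet, fm.tissue)  # re-validate labels

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "face_index": np.arange(len(self)),
            "facet_id": self.facet,
            "tissue": self.tissue,
        }).to_csv(path, index=False)


@dataclass
class WearAreaProfile:
    """Absolute facet areas, TWA, and relative areas by phase (tip crush in phase II)."""

    absolute: dict = field(default_factory=dict)  # facet label -> mm^2
    twa: float = 0.0
    relative: dict = field(default_factory=dict)  # phase -> proportion of TWA

    def phase_absolute(self, phase: str) -> float:
        return sum(a for f, a in self.absolute.items() if PHASE_OF[f] == phase)


@dataclass
class InclinationProfile:
    """Per-phase inclinations (degrees), tip crush separate; NaN when a phase is absent."""

    by_phase: dict = field(default_factory=dict)   # phase -> degrees (NaN if missing)
    by_facet: dict = field(default_factory=dict)   # facet label -> degrees


def facet_areas(mesh: trimesh.Trimesh, facet_map: FacetMap) -> WearAreaProfile:
    """Absolute and relative wear-facet areas.

    TWA sums all worn facets including tip crush; dentine-flagged faces
    inside a facet count toward that facet (dentine exposed by wear is worn
    surface). Relative areas are reported per phase with tip crush merged
    into phase II; they sum to 1 whenever TWA > 0.
    """
    if len(facet_map) != len(mesh.faces):
        raise ValueError("facet map and mesh have different face counts")
    areas = mesh.area_faces
    absolute: dict[str, float] = {}
    for label in FACET_LABELS:
        if label == UNWORN:
            continue
        mask = facet_map.facet == label
        if mask.any():
            absolute[label] = float(areas[mask].sum())
    twa = float(sum(absolute.values()))
    if twa <= 0.0:
        raise UnwornSpecimenError("no worn facets: TWA = 0, relative areas undefined")
    by_phase = {p: 0.0 for p in PHASES}
    for label, a in absolute.items():
        phase = PHASE_OF[label]
        if phase == TIP_CRUSH:
            phase = PHASE_II  # merged for the area analysis
        by_phase[phase] += a
    relative = {p: a / twa for p, a in by_phase.items()}
    return WearAreaProfile(absolute=absolute, twa=twa, relative=relative)


def facet_inclination(mesh: trimesh.Trimesh, facet_map: FacetMap, facet: str,
                      cervical_normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, folded to [0, 90]) between a facet's best-fit plane
    and the cervical plane.

    The facet plane is a weighted total-least-squares fit over every vertex
    of the facet's triangles, each vertex weighted by one third of its
    summed incident facet-triangle areas — a deterministic, area-faithful
    analogue of an interactive best-fit-plane pick.
    """
    faces = facet_map.faces_of(facet)
    if faces.size == 0:
        raise MissingFacetError(facet)
    tri = mesh.faces[faces]
    tri_areas = mesh.area_faces[faces]
    vert_ids, inverse = np.unique(tri, return_inverse=True)
    weights = np.zeros(len(vert_ids))
    np.add.at(weights, inverse.reshape(tri.shape).ravel(), np.repeat(tri_areas / 3.0, 3))
    plane = fit_plane(mesh.vertices[vert_ids], weights=weights)
    n = np.asarray(cervical_normal, float)
    n = n / np.linalg.norm(n)
    c = abs(float(np.dot(plane.normal, n)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def phase_inclinations(mesh: trimesh.Trimesh, facet_map: FacetMap,
                       cervical_normal=(0.0, 0.0, 1.0), weighted: bool = True) -> InclinationProfile:
    """Per-phase summary of facet inclinations; tip crush kept separate.

    The phase value is the area-weighted mean of its member facets' angles
    (``weighted=False`` gives the unweighted mean). Phases with no worn
    facet are NaN, not zero.
    """
    profile = facet_areas(mesh, facet_map)
    by_facet = {f: facet_inclination(mesh, facet_map, f, cervical_normal)
                for f in profile.absolute}
    by_phase: dict[str, float] = {}
    for phase in (*PHASES, TIP_CRUSH):
        members = [f for f in by_facet if PHASE_OF[f] == phase]
        if not members:
            by_phase[phase] = math.nan
            continue
        angles = np.array([by_facet[f] for f in members])
        w = np.array([profile.absolute[f] for f in members]) if weighted else np.ones(len(members))
        by_phase[phase] = float(np.average(angles, weights=w))
    return InclinationProfile(by_phase=by_phase, by_facet=by_facet)


def dentine_area(mesh: trimesh.Trimesh, facet_map: FacetMap, face_weights=None) -> float:
    """Total dentine-flagged area (mm^2), optionally with per-face area weights
    (e.g. the clipped occlusal fractions)."""
    areas = mesh.area_faces if face_weights is None else np.asarray(face_weights, float)
    return float(areas[facet_map.dentine_mask].sum())
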