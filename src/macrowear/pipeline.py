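"""Per-specimen measurement driver: orientation -> facet metrics -> topography.

Ties the geometric modules together into the one function that produces a
specimen's row of the cohort table: relative wear areas by phase, phase
inclinations (tip crush separate), OR, PDE, PEW and the raw areas.
"""

from __future__ import annotations

import math

import numpy as np
import trimesh

from . import facets as fc
from .facets import FacetMap, UnwornSpecimenError, facet_areas, phase_inclinations
from .orientation import establish_frame
from .topography import occlusal_relief, percent_dentine_exposure, percent_enamel_wear

#: column order of a specimen row (cohort CSV schema v1)
SPECIMEN_COLUMNS = [
    "specimen", "taxon", "sex", "wear_stage",
    "area_buccal_pi", "area_lingual_pi", "area_phase_ii",
    "incl_buccal_pi", "incl_lingual_pi", "incl_phase_ii", "incl_tip_crush",
    "OR", "PDE", "PEW", "TWA", "occlusal_3d_area", "occlusal_2d_area",
]


def measure_specimen(mesh: trimesh.Trimesh, cervical_points: np.ndarray,
                     facet_map: FacetMap, manual_fossa=None,
                     weighted_inclinations: bool = True) -> dict:
    """Measure one labelled crown; returns a dict of the specimen metrics.

    An unworn crown (no labelled facets) yields zero PEW/PDE and missing
    (NaN) relative areas and inclinations rather than an error, so whole
    cohorts can be processed in one pass.
    """
    oriented, frame = establish_frame(mesh, cervical_points, manual_fossa=manual_fossa)
    oriented_map = FacetMap(facet_map.facet, facet_map.tissue)  # labels follow faces, not coordinates
    orr, a3d, a2d = occlusal_relief(oriented, frame.occlusal_plane)
    row: dict = {"OR": orr, "occlusal_3d_area": a3d, "occlusal_2d_area": a2d}
    row["PDE"] = percent_dentine_exposure(oriented, oriented_map, a3d, frame.occlusal_plane)
    try:
        profile = facet_areas(oriented, oriented_map)
    except UnwornSpecimenError:
        row.update(TWA=0.0, PEW=0.0,
                   area_buccal_pi=math.nan, area_lingual_pi=math.nan, area_phase_ii=math.nan,
                   incl_buccal_pi=math.nan, incl_lingual_pi=math.nan,
                   incl_phase_ii=math.nan, incl_tip_crush=math.nan)
        return row
    row["TWA"] = profile.twa
    row["PEW"] = percent_enamel_wear(profile, a3d)
    row["area_buccal_pi"] = profile.relative[fc.BUCCAL_PI]
    row["area_lingual_pi"] = profile.relative[fc.LINGUAL_PI]
    row["area_phase_ii"] = profile.relative[fc.PHASE_II]
    incl = phase_inclinations(oriented, oriented_map, weighted=weighted_inclinations)
    row["incl_buccal_pi"] = incl.by_phase[fc.BUCCAL_PI]
    row["incl_lingual_pi"] = incl.by_phase[fc.LINGUAL_PI]
    row["incl_phase_ii"] = incl.by_phase[fc.PHASE_II]
    row["incl_tip_crush"] = incl.by_phase[fc.TIP_CRUSH]
    return row
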