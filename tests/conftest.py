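"""Shared fixtures: tiny hand-written mesh files and synthetic crowns.

All fixtures are generated programmatically; nothing binary ships with the
test suite.
"""

import numpy as np
import pytest

import macrowear as mw

UNIT_SQUARE_PLY = """\
ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 2
property list uchar int vertex_indices
end_header
0 0 0
1 0 0
1 1 0
0 1 0
3 0 1 2
3 0 2 3
"""

UNIT_SQUARE_OBJ = """\
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
f 1 2 3
f 1 3 4
"""

UNIT_SQUARE_STL = """\
solid square
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 1 1 0
  endloop
endfacet
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 1 0
    vertex 0 1 0
  endloop
endfacet
endsolid square
"""

BAD_INDEX_PLY = UNIT_SQUARE_PLY.replace("3 0 2 3", "3 0 2 9")


@pytest.fixture
def square_files(tmp_path):
    paths = {}
    for name, text in [("square.ply", UNIT_SQUARE_PLY), ("square.obj", UNIT_SQUARE_OBJ),
                       ("square.stl", UNIT_SQUARE_STL), ("bad.ply", BAD_INDEX_PLY)]:
        p = tmp_path / name
        p.write_text(text)
        paths[name] = p
    return paths


@pytest.fixture(scope="session")
def crown():
    """One deterministic unworn crown with its cervical line and truth ledger."""
    return mw.generate_crown(mw.CrownSpec(seed=42))


@pytest.fixture(scope="session")
def carved_crown(crown):
    """A stage-2 worn crown: (worn mesh, cervical, facet map, ledger, truth)."""
    mesh, cervical, truth = crown
    plan = mw.default_facet_plan(2, rng=np.random.default_rng(42))
    worn, fmap, ledger = mw.carve_facets(mesh, plan, truth)
    return worn, cervical, fmap, ledger, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Three groups drawn from one distribution (calibration null)."""
    g = mw.GroupSpec(name="G. g. gorilla", n=15)
    groups = (g, mw.GroupSpec(name="G. b. graueri", n=15),
              mw.GroupSpec(name="G. b. beringei", n=15))
    same = tuple(
        mw.GroupSpec(name=grp.name, n=15) for grp in groups)
    return mw.generate_cohort(mw.CohortSpec(groups=same, seed=123))


def random_rigid_transform(rng):
    """Uniform random rotation + bounded translation as a 4x4 matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = np.eye(4)
    t[:3, :3] = rot
    t[:3, 3] = rng.uniform(-10, 10, size=3)
    return t
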