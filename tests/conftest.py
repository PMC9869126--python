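import numpy as np
import pytest
import trimesh

import aneuwall as aw
from aneuwall.mesh import TriangleMesh


def _cube_mesh() -> TriangleMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices, float) + 0.5,
                        np.asarray(box.faces, np.int64))


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    return _cube_mesh()


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriangleMesh(np.asarray(ico.vertices, float),
                        np.asarray(ico.faces, np.int64))


@pytest.fixture(scope="session")
def default_pair() -> aw.ModelPair:
    """One default synthetic aneurysm, shared across tests."""
    return aw.make_model_pair(aw.AneurysmSpec())


@pytest.fixture(scope="session")
def default_inflation(default_pair):
    sac, _ = aw.split_at_neck(default_pair.model_a, default_pair.neck_curve)
    patch, _ = aw.split_at_neck(default_pair.model_b, default_pair.neck_curve)
    result = aw.inflate_to_mold(patch, sac)
    return sac, patch, result


@pytest.fixture(scope="session")
def table1() -> aw.CohortTable:
    return aw.load_table1()
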