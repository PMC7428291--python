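import numpy as np
import pytest

import graspsel as gs


@pytest.fixture(scope="session")
def bar_object():
    """10-cube wooden bar along x, coarse mesh (2 triangles/face)."""
    return gs.build_polycube(
        [(i, 0, 0) for i in range(10)], cube_edge=25.0, resolution="coarse",
        name="bar",
    )


@pytest.fixture(scope="session")
def l_object():
    """10-cube wooden L, coarse mesh."""
    coords = [(i, 0, 0) for i in range(6)] + [(0, j, 0) for j in range(1, 5)]
    return gs.build_polycube(coords, cube_edge=25.0, resolution="coarse", name="L")


@pytest.fixture(scope="session")
def heavy_l_object():
    """Bipartite 5-wood / 5-brass L (716 g), coarse mesh."""
    coords = [(i, 0, 0) for i in range(6)] + [(0, j, 0) for j in range(1, 5)]
    mats = ["brass"] * 5 + ["wood"] * 5
    return gs.build_polycube(coords, mats, cube_edge=25.0, resolution="coarse",
                             name="L-heavy")


@pytest.fixture(scope="session")
def tower_object():
    """Two stacked cubes: the grasp axis is free to rotate about z."""
    return gs.build_polycube([(0, 0, 0), (0, 0, 1)], cube_edge=25.0,
                             resolution="coarse", name="tower")


@pytest.fixture(scope="session")
def config():
    return gs.ModelConfig()


@pytest.fixture(scope="session")
def bar_candidates(bar_object, config):
    return gs.candidate_contacts(bar_object, config.table_z)


@pytest.fixture(scope="session")
def l_candidates(l_object, config):
    return gs.candidate_contacts(l_object, config.table_z)


@pytest.fixture(scope="session")
def l_maps(l_candidates, l_object, config):
    return gs.compute_penalty_maps(l_candidates, l_object, config)


@pytest.fixture(scope="session")
def l_overall(l_maps):
    return gs.combine(l_maps)


def make_candidates(positions, normals):
    """Hand-built candidate set for closed-form penalty checks."""
    positions = np.asarray(positions, dtype=float)
    normals = np.asarray(normals, dtype=float)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    n = len(positions)
    from graspsel.object_model import CandidateSet

    return CandidateSet(positions, normals, np.ones(n), np.arange(n))
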