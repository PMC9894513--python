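import numpy as np
import pytest
import trimesh

from palatosym import PalateParams, generate_palate


@pytest.fixture
def tetra() -> trimesh.Trimesh:
    """Unit tetrahedron: the smallest closed triangle mesh."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


@pytest.fixture(scope="session")
def coarse_sphere() -> trimesh.Trimesh:
    """Unit icosphere with < 200 faces, for exhaustive-oracle comparisons."""
    return trimesh.creation.icosphere(subdivisions=1)


@pytest.fixture(scope="session")
def palate_symmetric():
    return generate_palate(PalateParams(mesh_resolution=48))


@pytest.fixture(scope="session")
def palate_asymmetric():
    return generate_palate(PalateParams(mesh_resolution=48, asymmetry_amplitude=1.0))


def random_rigid(rng: np.random.Generator):
    """A uniformly random proper rotation + translation, for equivariance checks."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t
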