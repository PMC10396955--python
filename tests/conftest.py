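import numpy as np
import pytest

from evpkit import BuildRecipe, build_cage_3d, build_ortho_benzene


@pytest.fixture(scope="session")
def oxa_model():
    """Seed-fixed minimized 3D model of the phenyl/carboxyl oxa cage."""
    return build_cage_3d(BuildRecipe("oxa_bch", seed=7, n_conformers=20))


@pytest.fixture(scope="session")
def bcp_model():
    return build_cage_3d(BuildRecipe("bcp_12", seed=7, n_conformers=20))


@pytest.fixture(scope="session")
def bch_model():
    return build_cage_3d(BuildRecipe("bch_12", seed=7, n_conformers=20))


@pytest.fixture()
def benzene_model():
    return build_ortho_benzene(a=1.39, b=1.50)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix (QR with det fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
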