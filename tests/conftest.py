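import numpy as np
import pytest
from scipy.stats import ortho_group

import ctrldiff as cd
from ctrldiff.network import init_params


@pytest.fixture(scope="session")
def minimal_set():
    return cd.generate_fixtures("minimal")


@pytest.fixture(scope="session")
def chains_set():
    return cd.generate_fixtures("chains", k=5)


@pytest.fixture(scope="session")
def tiny_arch():
    return cd.LayerConfig(width=32, n_layers=2, n_heads=2)


@pytest.fixture(scope="session")
def short_schedule():
    return cd.NoiseParams(T=30)


@pytest.fixture(scope="session")
def tiny_params(tiny_arch):
    return init_params(tiny_arch, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """A proper random rotation matrix (det +1)."""
    q = ortho_group.rvs(3, random_state=rng)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotate_graph(graph, Q, translation=None):
    coords = graph.coords @ Q.T
    if translation is not None:
        coords = coords + translation
    return cd.Molecule3DGraph(
        coords, graph.atom_types, graph.charges, graph.bonds, id=graph.id, vocab=graph.vocab
    )
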