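import numpy as np
import pytest

from nucleopack.geometry import NucleosomePose
from nucleopack.synthetic import gen_condensate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_pose(center, normal, dyad=None, id=0):
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if dyad is None:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, normal)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        dyad = np.cross(normal, helper)
    return NucleosomePose(center=np.asarray(center, dtype=float), normal=normal,
                          dyad=np.asarray(dyad, dtype=float) / np.linalg.norm(dyad),
                          id=id)


def random_pose(rng, center_scale=10.0, id=0):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return NucleosomePose(center=rng.normal(scale=center_scale, size=3),
                          normal=q[:, 2], dyad=q[:, 0], id=id)


@pytest.fixture(scope="session")
def small_bp30_condensate():
    """~360-nucleosome two-start condensate at the nuclear density."""
    return gen_condensate(fiber_kind="bp30_like", n_fibers=30,
                          target_density=6.0e5, seed=42)
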