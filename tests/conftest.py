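import numpy as np
import pytest

from confens import synthetic
from confens.structio import Ensemble


@pytest.fixture(scope="session")
def helix20():
    model, truth = synthetic.gen_canonical_ss("helix", 20)
    return model


@pytest.fixture(scope="session")
def helix30():
    model, _ = synthetic.gen_canonical_ss("helix", 30)
    return model


@pytest.fixture(scope="session")
def hairpin8():
    model, _ = synthetic.gen_canonical_ss("hairpin", 8)
    return model


@pytest.fixture(scope="session")
def single_frame_helix(helix20):
    return Ensemble(topology=helix20, frames=[helix20.coords])


def random_rigid_motion(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-15, 15, size=3)
    return rot, trans
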