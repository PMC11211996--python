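import numpy as np
import pytest

from netspread import Connectome, SyntheticWorld, synth_connectome, synth_pathology


@pytest.fixture(scope="session")
def world():
    """Default 68-region 4-modality synthetic study."""
    return SyntheticWorld.default(rng_seed=7)


@pytest.fixture(scope="session")
def measured(world):
    return synth_pathology(world)


@pytest.fixture(scope="session")
def small_connectome():
    return synth_connectome(10, "distance", rng_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connected_connectome(n: int, rng: np.random.Generator,
                                density: float = 0.5) -> Connectome:
    """Random weighted connectome guaranteed connected via a ring backbone."""
    w = rng.uniform(0.1, 1.0, size=(n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    for i in range(n):
        w[min(i, (i + 1) % n), max(i, (i + 1) % n)] = rng.uniform(0.5, 1.0)
    w = w + w.T
    half = n // 2
    labels = [f"lh_region{i:03d}" for i in range(half)] + [
        f"rh_region{i:03d}" for i in range(n - half)
    ]
    return Connectome(w, labels, "random")
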