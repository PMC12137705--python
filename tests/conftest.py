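import numpy as np
import pytest

from couplemap import StructuralConnectome


def random_sc(
    n: int,
    rng: np.random.Generator,
    density: float = 0.5,
    participant_id: str = "sub-test",
) -> StructuralConnectome:
    """Random connected weighted SC with continuous (tie-free) weights."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.uniform(size=len(iu[0])) < density
    weights = rng.lognormal(0.0, 0.8, size=len(iu[0]))
    w[iu] = np.where(present, weights, 0.0)
    w += w.T
    # ring lattice guarantees connectivity without introducing weight ties
    for i in range(n):
        j = (i + 1) % n
        if w[i, j] == 0:
            w[i, j] = w[j, i] = rng.lognormal(0.0, 0.8)
    return StructuralConnectome(participant_id, w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sc(rng):
    return random_sc(8, rng)
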