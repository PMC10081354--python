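import numpy as np
import pytest

from spdmean.geometry import matrix_expm, sym


def random_spd(rng, p, scale=1.0):
    """Moderately conditioned random SPD matrix: expm of a scaled GOE draw."""
    e = sym(rng.standard_normal((p, p))) / np.sqrt(p)
    return matrix_expm(scale * e)


def random_spd_stack(rng, n, p, scale=1.0):
    return np.stack([random_spd(rng, p, scale) for _ in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def spd_factory():
    return random_spd


@pytest.fixture
def spd_stack_factory():
    return random_spd_stack
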