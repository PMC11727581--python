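import numpy as np
import pytest

from retroseeker.detect import DetectParams
from retroseeker.simulate import SimConfig, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params():
    return DetectParams()


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulation shared across read-only tests."""
    config = SimConfig(genome_length=300_000, n_true=20, n_control=10, seed=7)
    return config, run_simulation(config)


def random_seq(rng, n, bases="ACGT"):
    return "".join(bases[i] for i in rng.integers(0, len(bases), size=n))
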