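import numpy as np
import pytest

from ministep.data_model import BehaviorScale, Wave, WavePanel
from ministep.effects import Effect, EffectSpec
from ministep.engine import ParameterVector, SaomModel


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)


def random_graph(rng, n, density=0.4):
    x = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(x, 0)
    return x


@pytest.fixture
def toy_panel():
    """3 actors, 2 waves: wave 1 has the single tie A->B; wave 2 adds B->A."""
    x1 = np.zeros((3, 3), dtype=np.int8)
    x1[0, 1] = 1
    x2 = x1.copy()
    x2[1, 0] = 1
    z1 = np.array([3.0, 5.0, 7.0])
    z2 = np.array([4.0, 5.0, 7.0])
    part = np.ones(3, dtype=bool)
    return WavePanel(["A", "B", "C"],
                     [Wave(x1, z1, part.copy()), Wave(x2, z2, part.copy())])


@pytest.fixture(scope="session")
def small_model():
    spec = EffectSpec([
        Effect("network", "outdegree"),
        Effect("network", "reciprocity"),
        Effect("behavior", "linear_shape"),
        Effect("behavior", "average_similarity"),
    ])
    scale = BehaviorScale(11, 6.0, 10.0)
    return SaomModel(spec, scale, sim_c=0.0)


@pytest.fixture(scope="session")
def simulated_panel(small_model):
    """A panel simulated from known parameters, reused across tests."""
    rng = np.random.default_rng(42)
    n = 40
    theta = ParameterVector([3.0, 3.0, 3.0], [1.5, 1.5, 1.5],
                            [-2.0, 1.5], [0.2, 3.0])
    x0 = random_graph(rng, n, density=0.08)
    z0 = rng.integers(3, 10, size=n).astype(float)
    panel = small_model.simulate_panel(x0, z0, theta, 3, rng)
    return panel, theta
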