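import numpy as np
import pytest

from symptomnet.core_model import SymptomNetwork
from symptomnet.synthetic_data import GeneratorSpec, random_network


@pytest.fixture(scope="session")
def default_network() -> SymptomNetwork:
    """The package's reference 14-symptom synthetic network (seed 1)."""
    return random_network(GeneratorSpec(seed=1))


@pytest.fixture
def two_node_network() -> SymptomNetwork:
    return SymptomNetwork(
        labels=("a", "b"),
        weights=np.array([[0.0, 0.8], [0.8, 0.0]]),
        thresholds=np.array([-1.0, 0.5]),
    )


@pytest.fixture
def uncoupled_network() -> SymptomNetwork:
    """Six symptoms, no edges, thresholds -5 (b = 5 under the default mode)."""
    J = 6
    return SymptomNetwork(
        labels=tuple(f"S{i}" for i in range(J)),
        weights=np.zeros((J, J)),
        thresholds=np.full(J, -5.0),
    )


def make_sparse_network(J: int, density: float, weight_range, threshold_range, seed: int) -> SymptomNetwork:
    """Random positive-weight test network (independent of the generator module)."""
    rng = np.random.default_rng(seed)
    W = np.zeros((J, J))
    iu, ju = np.triu_indices(J, k=1)
    present = rng.random(len(iu)) < density
    w = rng.uniform(*weight_range, size=len(iu)) * present
    W[iu, ju] = w
    W[ju, iu] = w
    tau = rng.uniform(*threshold_range, size=J)
    return SymptomNetwork(labels=tuple(f"S{i}" for i in range(J)), weights=W, thresholds=tau)
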