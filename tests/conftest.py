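import numpy as np
import pytest

from paingate import GateCircuit, shift_from_threshold


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_circuit():
    """Circuit frozen at the standard converged point: weights (1, 0, 0.5, 0.5),
    thresholds (0.51, 0.02)."""
    return GateCircuit.from_values(
        [1.0, 0.0, 0.5, 0.5],
        [shift_from_threshold(0.51), shift_from_threshold(0.02)],
        synaptic_plasticity_on=False,
        intrinsic_plasticity_on=False,
    )
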