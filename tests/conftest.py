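import numpy as np
import pytest

from brainsim import Connectome, generate_synthetic_connectome


@pytest.fixture
def small_connectome():
    """4-node connectome with hand-picked weights and lengths."""
    weights = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [3.0, 0.0, 0.0, 1.0],
            [0.0, 2.0, 0.0, 2.0],
            [1.0, 0.0, 1.0, 0.0],
        ]
    )
    lengths = np.array(
        [
            [0.0, 10.0, 20.0, 30.0],
            [10.0, 0.0, 15.0, 25.0],
            [20.0, 15.0, 0.0, 5.0],
            [30.0, 25.0, 5.0, 0.0],
        ]
    )
    return Connectome(weights=weights, tract_lengths=lengths, speed=4.0)


@pytest.fixture
def demo_connectome():
    """74-node two-hemisphere synthetic connectome (integer weights 0-3)."""
    return generate_synthetic_connectome(n_regions=74, weight_levels=4, seed=42)
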