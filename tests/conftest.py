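import numpy as np
import pytest

from bemdmf import BoxCountingConfig, generate_slow_fast_signal
from bemdmf.synthetic import CascadeSpec, generate_binomial_cascade

CASCADE_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def pow2_boxes() -> BoxCountingConfig:
    """Box sizes that divide dyadic image sides exactly (no partial boxes)."""
    return BoxCountingConfig(box_sizes=(2, 4, 8, 16, 32, 64))


@pytest.fixture(scope="session")
def demo_signal():
    """Noise-free slow/fast oscillation test image, 64x64."""
    return generate_slow_fast_signal(64, noise_sd=0.0)


@pytest.fixture(scope="session")
def cascade_128() -> np.ndarray:
    return generate_binomial_cascade(CascadeSpec(CASCADE_WEIGHTS, depth=7, seed=0))


@pytest.fixture(scope="session")
def cascade_64() -> np.ndarray:
    return generate_binomial_cascade(CascadeSpec(CASCADE_WEIGHTS, depth=6, seed=0))
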