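import numpy as np
import pytest

from muscleperf.kinetics import Curve
from muscleperf.simulate import AIFSpec, generate_aif


@pytest.fixture(scope="session")
def aif() -> Curve:
    """A well-conditioned gamma-variate AIF with recirculation, 40 frames at 1 s."""
    return generate_aif(AIFSpec(peak_amplitude=6.0, arrival_time=3.0,
                                shape_alpha=3.0, shape_beta=1.5,
                                recirculation_fraction=0.15))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
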