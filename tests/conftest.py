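import numpy as np
import pytest

from pcgscreen import PcgSignal, generate_pcg, preset


@pytest.fixture(scope="session")
def healthy_signal() -> PcgSignal:
    return generate_pcg(preset("healthy", seed=0))


@pytest.fixture(scope="session")
def unhealthy_signal() -> PcgSignal:
    return generate_pcg(preset("unhealthy", seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
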