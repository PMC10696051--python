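import numpy as np
import pytest

from tempovar.sbp_exact import GrowthParams


@pytest.fixture
def unit_rate() -> GrowthParams:
    return GrowthParams(mu=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
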