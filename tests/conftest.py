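import numpy as np
import pytest

from duotank import (
    DimensionlessFit,
    PowerLawTransfer,
    RecircParams,
    SaturationLaw,
)


@pytest.fixture
def transfer():
    return PowerLawTransfer()


@pytest.fixture
def sat():
    return SaturationLaw()


@pytest.fixture
def rp():
    return RecircParams()


@pytest.fixture
def dimfit():
    return DimensionlessFit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
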