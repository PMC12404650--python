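import numpy as np
import pytest

from cuttlefield import (
    CardLayout,
    WaterOpticsParams,
    fit_attenuation,
    render_card_series,
)

TRUE_K = (0.5, 0.07, 0.04)


@pytest.fixture(scope="session")
def layout() -> CardLayout:
    return CardLayout.default()


@pytest.fixture(scope="session")
def optics() -> WaterOpticsParams:
    return WaterOpticsParams(k=TRUE_K, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_series(optics, layout):
    return render_card_series(optics, layout)


@pytest.fixture(scope="session")
def fitted_model(noiseless_series):
    return fit_attenuation(noiseless_series)


@pytest.fixture
def rng():
    return np.random.default_rng(20241111)
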