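import numpy as np
import pytest

from gradplate import default_layout, preset, process_plates, simulate_plates


@pytest.fixture
def layout():
    """Standard 8 x 12 layout with the 60.1 ± 19.9 °C gradient."""
    return default_layout()


@pytest.fixture
def layout_55(scope="session"):
    """Standard layout with the 55.0 ± 19.9 °C gradient."""
    return default_layout(center=55.0, span=19.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def noiseless_landscape(layout_55):
    """Landscape processed from noiseless synthetic triplicates."""
    params = preset("celluclast-like", noise_sd=0.0)
    readings, blank = simulate_plates(params, layout_55)
    return process_plates(readings, blank, layout_55)
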