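import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from thzmodes import microcystin_aptamer
from thzmodes.synthetic import SpectrometerConfig, gen_spectrometer_run


@pytest.fixture(scope="session")
def aptamer_seq():
    return microcystin_aptamer()


@pytest.fixture(scope="session")
def noiseless_run():
    """Blank/buffer/sample triplet with the published ~829 GHz signature."""
    return gen_spectrometer_run(SpectrometerConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(534)
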