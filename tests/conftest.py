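import numpy as np
import pytest

from isopulse.simulate import PlotDesign, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230716)


@pytest.fixture
def sim_config():
    """Default study-condition generator config with a fixed seed."""
    return SimConfig(seed=20230716)


@pytest.fixture
def unwarmed_plot():
    return PlotDesign("U1", warming_dt=0.0, n_addition=0)


@pytest.fixture
def warmed_plot():
    return PlotDesign("U7", warming_dt=8.7, n_addition=0)
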