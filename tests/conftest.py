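import numpy as np
import pytest

from spindlebox import (
    PlotGeometry,
    SimulationConfig,
    render_dataset,
    simulate_record,
)


@pytest.fixture(scope="session")
def short_sim():
    """A 2-minute simulated record with both event types (seed-fixed)."""
    record, annotations = simulate_record(SimulationConfig(duration_s=120.0, seed=7))
    return record, annotations


@pytest.fixture(scope="session")
def rendered(short_sim):
    record, annotations = short_sim
    geometry = PlotGeometry()
    images = render_dataset(record, annotations, geometry)
    return record, annotations, geometry, images


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
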