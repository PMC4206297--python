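import numpy as np
import pytest

from irifcyto import (
    SimulationConfig,
    analyze_nuclei,
    mask_target,
    pixel_histogram,
    segment_nuclei,
    simulate_field,
)


@pytest.fixture(scope="session")
def base_config():
    """Default-noise unirradiated field, 10 nuclei in 512x512."""
    return SimulationConfig(model="unirradiated", n_nuclei=10, seed=1)


@pytest.fixture(scope="session")
def noise_free_config(base_config):
    return base_config.with_(noise=False)


def histogram_of(config):
    """Simulate, segment and pool the target-channel pixel histogram."""
    fov, _truth = simulate_field(config)
    mask = segment_nuclei(fov.dapi)
    return pixel_histogram(mask_target(fov.target, mask), condition=config.label)


def records_of(config):
    """Simulate, segment and produce per-nucleus intensity records."""
    fov, truth = simulate_field(config)
    mask = segment_nuclei(fov.dapi)
    return analyze_nuclei(fov.target, mask), truth


@pytest.fixture(scope="session")
def degradation_pair():
    """(NoIR histogram, IR degradation s=0.2 histogram) with default noise."""
    base = SimulationConfig(model="unirradiated", n_nuclei=10, seed=11)
    h0 = histogram_of(base)
    h1 = histogram_of(base.with_(model="degradation", survival_fraction=0.2, seed=12))
    return h0, h1
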