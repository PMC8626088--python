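import numpy as np
import pytest

from connatlas.benchmarks import study_axon_world, study_detection_params
from connatlas.synthetic import (
    SimulationConfig,
    add_background_and_noise,
    make_toy_atlas,
    simulate_somata,
)

# Study conditions used across the suite: clip floor = amplitude / 3, the
# "predetermined threshold range" analog for the synthetic tracer brightness.
STUDY_DETECTION = study_detection_params(SimulationConfig())


@pytest.fixture(scope="session")
def toy_atlas():
    """Small 6-region atlas for unit tests."""
    return make_toy_atlas((60, 60, 60), 6, seed=7)


@pytest.fixture(scope="session")
def study_atlas():
    """Full-size 8-region study atlas (100 µm cube at 1 µm)."""
    return make_toy_atlas((100, 100, 100), 8, seed=1)


@pytest.fixture(scope="session")
def axon_study():
    """One simulated axon study (selective targets) with noise and truth."""
    return study_axon_world(seed=1)


@pytest.fixture(scope="session")
def soma_study(study_atlas):
    """One simulated soma volume with noise, plus its ground truth."""
    annotation, table = study_atlas
    cfg = SimulationConfig(seed=2)
    vol, truth = simulate_somata(annotation, table, cfg)
    noisy = add_background_and_noise(vol, cfg)
    return annotation, table, cfg, noisy, truth
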