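import pytest

import glovecal as gc
from glovecal.bpnn import NetworkConfig


@pytest.fixture(scope="session")
def neutral_fit():
    return gc.HandFitProfile.neutral()


@pytest.fixture(scope="session")
def affine_truth():
    """Perfectly linear, noiseless index-MCP sensor."""
    return gc.SensorGroundTruth(sensor_id="index_mcp", r_flat=1201, gain=1500)


@pytest.fixture(scope="session")
def curved_truth():
    """Strongly nonlinear, noiseless index-MCP sensor."""
    return gc.SensorGroundTruth(
        sensor_id="index_mcp", r_flat=1201, gain=1500, curvature=3.0
    )


@pytest.fixture(scope="session")
def fast_cfg():
    """Tiny epoch budget for tests that only exercise plumbing."""
    return NetworkConfig(epochs=2000, subset_epochs=300, seed=5)


@pytest.fixture(scope="session")
def affine_results(affine_truth, neutral_fit):
    """Full-budget fit of the affine sensor (shared across tests)."""
    model = gc.SensorCalibration.from_simulation(
        affine_truth, neutral_fit, config=NetworkConfig(seed=3)
    )
    return model.fit()


@pytest.fixture(scope="session")
def curved_results(curved_truth, neutral_fit):
    """Full-budget fit of the nonlinear sensor (shared across tests)."""
    model = gc.SensorCalibration.from_simulation(
        curved_truth, neutral_fit, config=NetworkConfig(seed=3)
    )
    return model.fit()
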