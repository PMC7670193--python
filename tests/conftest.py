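"""Shared fixtures: reference parameter sets and cached expensive runs."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from blisterdry import (
    BlisterGeometry,
    KvPressureModel,
    RpModel,
    SyntheticSpec,
    load_reference_config,
    optimize_trajectory,
    simulate_protocol,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> BlisterGeometry:
    """Reference blister pocket: 40.5 x 23.5 x 7.2 mm."""
    return BlisterGeometry(
        total_length=40.5e-3, chord_length=23.5e-3, height=7.2e-3
    )


@pytest.fixture(scope="session")
def kv_edge() -> KvPressureModel:
    return KvPressureModel(
        alpha=10.1917, beta=1.1408, gamma=0.0614, population="edge"
    )


@pytest.fixture(scope="session")
def kv_center() -> KvPressureModel:
    return KvPressureModel(
        alpha=12.7208, beta=0.3015, gamma=0.0261, population="center"
    )


@pytest.fixture(scope="session")
def rp_highdose() -> RpModel:
    return RpModel(rp0=7.05e4, a=1.92e8, b=-68.30)


@pytest.fixture(scope="session")
def highdose_config():
    return load_reference_config("highdose")


@pytest.fixture(scope="session")
def traditional_result(highdose_config):
    """Traditional ramp-and-hold cycle simulated with center Kv."""
    return simulate_protocol(
        highdose_config.build_protocol(), highdose_config.build_setup("center")
    )


@pytest.fixture(scope="session")
def optimized_result(highdose_config):
    """Dynamically optimized trajectory for the high-dose product."""
    return optimize_trajectory(
        highdose_config.build_setup("edge"),
        highdose_config.build_setup("center"),
        highdose_config.build_limits(),
        collapse_temp=highdose_config.collapse_temperature,
        initial_shelf_temp=highdose_config.initial_shelf_temp,
    )


@pytest.fixture(scope="session")
def noiseless_synthetic_spec() -> SyntheticSpec:
    """Generator ground truth with every noise source switched off."""
    return SyntheticSpec(
        kv_dispersion=0.0,
        temperature_sigma=0.0,
        weighing_sigma=0.0,
        ratio_sigma=0.0,
        seed=1234,
    )


@pytest.fixture(scope="session")
def noiseless_process_trace(noiseless_synthetic_spec):
    """Zero-noise conservative-cycle trace plus its truth record."""
    from blisterdry import generate_process_trace

    return generate_process_trace(noiseless_synthetic_spec)
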