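"""Shared fixtures: one small network realization reused across the suite.

The resolution-2 sphere (320 pial outlets) is the workhorse for solver and
thrombus tests; acceptance tests that need the default desk-scale world
(resolution 3, 1280 outlets) build their own runs.
"""

import pytest

import collateralflow as cf


@pytest.fixture(scope="session")
def config_small() -> cf.ModelConfig:
    return cf.ModelConfig(
        network=cf.NetworkConfig(surface_resolution=2, seed=1,
                                 collateral_probability=0.25))


@pytest.fixture(scope="session")
def healthy_small(config_small):
    """Calibrated, autoregulated healthy baseline on the small network."""
    return cf.healthy_run(config_small)


@pytest.fixture(scope="session")
def occluding_outcome(healthy_small):
    """Fully occluding right-MCA clot on the small network."""
    vid = healthy_small.network.meta["thrombus_vessel"]
    return cf.stroke_run(healthy_small, cf.Thrombus(vid, 10.0, 0.0))
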