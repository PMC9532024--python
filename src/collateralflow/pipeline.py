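"""High-level simulation pipeline: generate -> calibrate -> healthy baseline.

The healthy state bundles everything a stroke simulation reuses: the
undiscretized network, the discretized solver model with boundary-
calibrated and autoregulated outlet resistances, and the converged healthy
result that later serves as the per-outlet perfusion baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .autoregulation import autoregulate
from .config import ModelConfig
from .generate import generate_network
from .haemodynamics import FlowModel, SimulationResult
from .network import VascularNetwork, discretize

logger = logging.getLogger(__name__)

#: discretization bounds: at least three nodes per vessel, spacing <= 2.5 mm
MAX_DX_MM = 2.5
MIN_NODES = 3


@dataclass
class HealthyState:
    """A calibrated, autoregulated healthy simulation and its ingredients."""

    config: ModelConfig
    network: VascularNetwork          # undiscretized
    disc_network: VascularNetwork
    model: FlowModel                  # holds calibrated outlet resistances
    result: SimulationResult
    calibration_scale: float


def healthy_run(config: ModelConfig,
                network: VascularNetwork | None = None) -> HealthyState:
    """Generate (or take) a network and produce the healthy baseline.

    Order of operations: discretize, initialize outlet resistances at the
    autoregulation set point, calibrate the inlet boundary by uniform
    outlet-resistance scaling (runs once, on the healthy network only),
    then autoregulate to the constant per-outlet flow target.
    """
    config.validate()
    if network is None:
        network = generate_network(config.network)
    disc = discretize(network, MAX_DX_MM, MIN_NODES)
    model = FlowModel(disc, config.solver)
    model.initialize_outlet_resistances(config.autoregulation.Q_brain_ml_s)
    scale = model.calibrate_inlet_boundary()
    result = autoregulate(model, config.solver, config.autoregulation)
    result.diagnostics["calibration_scale"] = scale
    logger.info("healthy baseline: N_total=%d, total pial flow %.4f ml/s",
                model.n_total, result.diagnostics["total_pial_flow_ml_s"])
    return HealthyState(config, network, disc, model, result, scale)
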