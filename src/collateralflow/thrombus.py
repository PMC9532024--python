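"""Permeable thrombus as a Darcy porous segment.

Integrated over the occluded span, Darcy's law gives the volumetric flow
Q = (kappa A / mu L) dp, i.e. a hydraulic resistance

    R_thrombus = mu L / (kappa A),

in series with the ordinary viscous resistance of the host vessel over the
same span: R_T = R_thrombus + R_vessel.  A fully occluding clot
(kappa = 0) is implemented as exact segment removal (zero conductance),
not a large finite resistance.  The thrombosed span is rigid: it is
excluded from elastic radius updates, and the Darcy law replaces the
velocity-profile assumption inside the clot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .config import ModelConfig, SolverConfig
from .haemodynamics import FlowModel, SimulationResult, conductance
from .network import VascularNetwork, discretize
from .pipeline import MAX_DX_MM, MIN_NODES, HealthyState, healthy_run
from .units import PA_S_PER_M3_TO_ML

logger = logging.getLogger(__name__)

#: sentinel resistance of a fully occluding thrombus
FULLY_OCCLUDING = math.inf


@dataclass
class Thrombus:
    """Occlusion descriptor on a host vessel.

    ``permeability_mm2`` of 0 (or None) means fully occluding.  The Darcy
    cross-section defaults to the host vessel's reference lumen area
    pi r0^2.
    """

    vessel_id: int
    length_mm: float
    permeability_mm2: float | None = 0.0
    cross_section_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("thrombus length must be > 0")
        if self.permeability_mm2 is not None and self.permeability_mm2 < 0:
            raise ValueError("permeability must be >= 0")


def darcy_resistance(kappa_mm2: float, area_mm2: float, length_mm: float,
                     viscosity_Pa_s: float) -> float:
    """Darcy resistance mu L / (kappa A) in Pa s/ml.

    kappa = 0 returns the fully-occluding sentinel (infinity); the solver
    then removes the segment's conductance entirely.
    """
    if area_mm2 <= 0 or length_mm <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("area, length and viscosity must be > 0")
    if kappa_mm2 < 0:
        raise ValueError("permeability must be >= 0")
    if kappa_mm2 == 0:
        return FULLY_OCCLUDING
    # SI: Pa s * m / (m^2 * m^2) = Pa s / m^3, then -> Pa s/ml
    r_si = viscosity_Pa_s * (length_mm * 1e-3) / ((kappa_mm2 * 1e-6) * (area_mm2 * 1e-6))
    return r_si * PA_S_PER_M3_TO_ML


def vessel_resistance(r_mm: float, length_mm: float,
                      config: SolverConfig) -> float:
    """Viscous resistance of a healthy vessel span (reference radius), Pa s/ml."""
    g = conductance(r_mm, length_mm, config.viscosity_Pa_s, config.zeta)
    return (1.0 / g) * PA_S_PER_M3_TO_ML


def total_segment_resistance(thrombus: Thrombus, host_r0_mm: float,
                             host_length_mm: float,
                             config: SolverConfig) -> float:
    """Total resistance of the vessel segment containing the thrombus.

    R_T = R_thrombus(kappa, L_clot) + R_vessel, where R_vessel is the
    viscous resistance of the whole host vessel.  Because the host vessel's
    conductance is replaced by 1/R_T wholesale, any (kappa, L) pair with
    the same R_T produces an identical system — pressure drop and flow
    collapse onto a single function of R_T.
    """
    if thrombus.length_mm > host_length_mm + 1e-12:
        raise ValueError(
            f"thrombus ({thrombus.length_mm} mm) longer than host vessel "
            f"({host_length_mm} mm)")
    area = thrombus.cross_section_mm2 or math.pi * host_r0_mm ** 2
    kappa = thrombus.permeability_mm2 or 0.0
    r_th = darcy_resistance(kappa, area, thrombus.length_mm, config.viscosity_Pa_s) \
        if kappa > 0 else FULLY_OCCLUDING
    if math.isinf(r_th):
        return FULLY_OCCLUDING
    return r_th + vessel_resistance(host_r0_mm, host_length_mm, config)


def apply_thrombus(network: VascularNetwork, thrombus: Thrombus,
                   config: SolverConfig) -> VascularNetwork:
    """Insert a thrombus into a (undiscretized) network.

    The whole host vessel is flagged ``thrombosed`` and its conductance is
    replaced by 1/R_T (distributed over its discretized segments in
    proportion to length); the thrombosed vessel is rigid.  The thrombus
    record is stored in ``network.meta['thrombus']``.  Raises KeyError for
    an unknown vessel and ValueError if the thrombus is longer than its
    host.
    """
    host = network.vessel_by_id(thrombus.vessel_id)  # KeyError if missing
    r_t = total_segment_resistance(thrombus, host.r0_mm, host.length_mm, config)
    nodes = [replace(n, position=n.position.copy()) for n in network.nodes]
    vessels = [replace(v, thrombosed=True, parent_id=v.id, arc_pos_mm=0.0)
               if v.id == host.id else replace(v)
               for v in network.vessels]
    out = VascularNetwork(nodes, vessels, network.brain_volume_ml,
                          dict(network.meta))
    out.meta["thrombus"] = {
        "vessel_id": host.id,
        "length_mm": thrombus.length_mm,
        "kappa_mm2": thrombus.permeability_mm2,
        "cross_section_mm2": thrombus.cross_section_mm2
        or math.pi * host.r0_mm ** 2,
        "territory": host.territory,
        "host_length_mm": host.length_mm,
        "R_T_Pa_s_ml": None if math.isinf(r_t) else r_t,
    }
    return out


def remove_thrombus(network: VascularNetwork) -> VascularNetwork:
    """Drop thrombus flags/overrides (the vessel split is kept; it is inert)."""
    vessels = [replace(v, thrombosed=False) for v in network.vessels]
    out = VascularNetwork([replace(n, position=n.position.copy())
                           for n in network.nodes],
                          vessels, network.brain_volume_ml, dict(network.meta))
    out.meta.pop("thrombus", None)
    return out


@dataclass
class StrokeOutcome:
    """One converged stroke simulation plus thrombus-level readouts."""

    result: SimulationResult
    thrombus: Thrombus
    R_T_Pa_s_ml: float
    dp_Pa: float
    Q_thrombus_ml_s: float
    Q_collateral_ml_s: float

    @property
    def Q_total_ml_s(self) -> float:
        return self.Q_thrombus_ml_s + self.Q_collateral_ml_s


def _thrombus_readouts(model: FlowModel, host_id: int,
                       affected: str) -> tuple[float, float, float]:
    """(dp across the clot span, Q through it, net collateral inflow), interface units."""
    p = model.P
    mask = model.thrombosed & (model.segment_parents == host_id)
    if not mask.any():
        raise RuntimeError("no thrombosed segments found in the model")
    idx = np.nonzero(mask)[0]
    # segments of the span are in series and ordered by construction
    q_si = model.segment_flows_SI()
    dp = float(p[model.seg_a[idx[0]]] - p[model.seg_b[idx[-1]]])
    q_th = float(q_si[idx[0]])
    # collateral inflow: flow across territory-crossing collateral segments
    terr_a = model._node_territory[model.seg_a]
    terr_b = model._node_territory[model.seg_b]
    cross = model.is_collateral & (terr_a != terr_b)
    into = np.where(terr_b == affected, 1.0,
                    np.where(terr_a == affected, -1.0, 0.0))
    q_coll = float(np.sum(q_si[cross] * into[cross]))
    return dp, q_th * 1e6, q_coll * 1e6  # m^3/s -> ml/s


def stroke_run(healthy: HealthyState, thrombus: Thrombus) -> StrokeOutcome:
    """Simulate a stroke on a healthy baseline's network.

    Outlet resistances start from the healthy calibrated/autoregulated
    state (boundary calibration is not repeated) and autoregulation then
    responds to the occlusion.
    """
    from .autoregulation import autoregulate

    cfg = healthy.config
    net = apply_thrombus(healthy.network, thrombus, cfg.solver)
    disc = discretize(net, MAX_DX_MM, MIN_NODES)
    model = FlowModel(disc, cfg.solver)
    # transfer healthy outlet resistances by outlet node id
    healthy_r = dict(zip(healthy.model.outlet_node_ids,
                         healthy.model.outlet_R_SI))
    model.outlet_R_SI = np.array([healthy_r[i] for i in model.outlet_node_ids])
    result = autoregulate(model, cfg.solver, cfg.autoregulation)
    r_t = net.meta["thrombus"]["R_T_Pa_s_ml"]
    dp, q_th, q_coll = _thrombus_readouts(
        model, thrombus.vessel_id, net.meta["thrombus"]["territory"])
    return StrokeOutcome(result, thrombus, math.inf if r_t is None else r_t,
                         dp, q_th, q_coll)


def sweep(config: ModelConfig, thrombus_lengths_mm, permeabilities_mm2,
          collateral_probabilities, seeds,
          vessel_id: int | None = None) -> pd.DataFrame:
    """Full stroke-simulation grid over clot length, permeability, collateral
    score and network seed.

    One healthy baseline per (probability, seed) network realization; one
    stroke simulation per grid point.  Solver failures are recorded in the
    ``error`` column and the sweep continues.
    """
    from .infarct import infarct_from_results

    rows = []
    for prob, seed in product(collateral_probabilities, seeds):
        cfg = replace(config,
                      network=replace(config.network, collateral_probability=prob,
                                      seed=seed))
        healthy = healthy_run(cfg)
        host_id = vessel_id if vessel_id is not None \
            else healthy.network.meta["thrombus_vessel"]
        for length, kappa in product(thrombus_lengths_mm, permeabilities_mm2):
            row = {"seed": seed, "collateral_probability": prob,
                   "L_mm": length, "kappa_mm2": kappa}
            try:
                th = Thrombus(host_id, length, kappa)
                outcome = stroke_run(healthy, th)
                iv, _ = infarct_from_results(healthy.result, outcome.result,
                                             cfg.infarct)
                row.update({
                    "R_T_Pa_s_ml": outcome.R_T_Pa_s_ml,
                    "dp_Pa": outcome.dp_Pa,
                    "Q_thrombus_ml_s": outcome.Q_thrombus_ml_s,
                    "Q_collateral_ml_s": outcome.Q_collateral_ml_s,
                    "Q_total_ml_s": outcome.Q_total_ml_s,
                    "infarct_ml": iv,
                    "error": "",
                })
            except Exception as exc:  # propagate per-point, keep sweeping
                logger.warning("sweep point failed (%s): %s", row, exc)
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
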