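"""Cerebral autoregulation as an outlet-resistance feedback loop.

Each penetrating-artery outlet adjusts its downstream resistance to hold
its flow at the common set point q = Q_brain / N_total:

    R = (P_i - P_out) / q,      clamped to [P_low / q, P_upp / q].

The clamps represent maximal dilation (low bound) and maximal
constriction (high bound) of the downstream vasculature.  All outlets are
updated synchronously from one solved pressure field; the full elastic
system is re-solved after every update, and the loop terminates when the
relative infinity-norm change of the outlet-resistance vector drops below
tolerance.  An optional damping factor stabilizes oscillatory cases
without moving the fixed point.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import AutoregulationConfig, SolverConfig
from .haemodynamics import ConvergenceError, FlowModel, SimulationResult
from .units import MMHG_TO_PA, ML_TO_M3

logger = logging.getLogger(__name__)


def target_outlet_flow(config: AutoregulationConfig, n_total: int) -> float:
    """Per-outlet flow set point q = Q_brain / N_total in ml/s."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return config.Q_brain_ml_s / n_total


def resistance_limits(config: AutoregulationConfig,
                      q_ml_s: float) -> tuple[float, float]:
    """(R_low, R_upp) in Pa s/ml: the maximal-dilation and -constriction bounds."""
    r_low = config.P_low_mmHg * MMHG_TO_PA / q_ml_s
    r_upp = config.P_upp_mmHg * MMHG_TO_PA / q_ml_s
    return r_low, r_upp


def update_outlet_resistance(P_i_Pa, P_out_Pa: float, q_ml_s: float,
                             config: AutoregulationConfig):
    """Resistance update R = (P_i - P_out)/q clamped to the physiological range.

    Accepts scalars or arrays; returns Pa s/ml.
    """
    if q_ml_s <= 0:
        raise ValueError("q_ml_s must be > 0")
    r = (np.asarray(P_i_Pa, dtype=float) - P_out_Pa) / q_ml_s
    r_low, r_upp = resistance_limits(config, q_ml_s)
    r = np.clip(r, r_low, r_upp)
    return r if r.ndim else float(r)


def autoregulate(model: FlowModel, solver_config: SolverConfig,
                 config: AutoregulationConfig) -> SimulationResult:
    """Iterate pial outlet resistances to the constant-flow set point.

    Non-pial (systemic) outlets keep their calibrated resistance.  The
    returned result's diagnostics record the iteration count, the final
    resistance residual, the unclamped-flow deviation from q and the
    clamp masks.
    """
    q_ml_s = target_outlet_flow(config, model.n_total)
    q_SI = q_ml_s * ML_TO_M3
    r_low, r_upp = resistance_limits(config, q_ml_s)
    pial = model.outlet_is_pial
    relax = config.relaxation
    history: list[float] = []
    if model.P is None:
        model.iterate_elastic()
    elastic_its = 0
    for it in range(1, config.max_iter + 1):
        p_i = model.P[model.outlet_idx[pial]]
        r_new_ml = update_outlet_resistance(
            p_i, solver_config.outlet_pressure_Pa, q_ml_s, config)
        r_new = r_new_ml * 1e6  # Pa s/ml -> Pa s/m^3
        r_old = model.outlet_R_SI[pial]
        r_next = (1 - relax) * r_old + relax * r_new
        eps = float(np.max(np.abs(r_next - r_old)) / np.max(np.abs(r_next)))
        model.outlet_R_SI[pial] = r_next
        its, _ = model.iterate_elastic()
        elastic_its += its
        history.append(eps)
        # flow deviation of unclamped outlets from the set point
        flows = model.outlet_flows_SI()[pial]
        r_now_ml = model.outlet_R_SI[pial] * 1e-6
        unclamped = (r_now_ml > r_low * (1 + 1e-9)) & (r_now_ml < r_upp * (1 - 1e-9))
        dev = float(np.max(np.abs(flows[unclamped] / q_SI - 1.0))) \
            if unclamped.any() else 0.0
        if eps < config.tol and dev < config.tol:
            logger.info("autoregulation converged: %d iterations "
                        "(%d elastic solves), eps_R=%.2e, flow dev=%.2e",
                        it, elastic_its, eps, dev)
            return model.result(
                iterations=it, residual=eps,
                extra_diagnostics={
                    "autoregulation_iterations": it,
                    "autoregulation_residual": eps,
                    "unclamped_flow_deviation": dev,
                    "n_clamped_low": int((r_now_ml <= r_low * (1 + 1e-9)).sum()),
                    "n_clamped_high": int((r_now_ml >= r_upp * (1 - 1e-9)).sum()),
                    "target_outlet_flow_ml_s": q_ml_s,
                })
        # oscillation fallback: if the residual stopped shrinking, damp harder
        if len(history) >= 6 and relax > 0.5 and history[-1] > history[-4]:
            relax = 0.5
            logger.debug("autoregulation: damping update (relaxation -> 0.5)")
    raise ConvergenceError(
        f"autoregulation did not converge in {config.max_iter} iterations",
        residual=history[-1] if history else None, history=history)
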