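"""Inversion of dynamic-CTA-style thrombus measurements.

From a patient's transit time dt, void fraction eps, thrombus length L and
contralateral lumen area A, the flow through the occluded segment is

    Q = eps * A * L / dt,

interpreted as contrast volume flux across the clot.  The model supplies,
per collateral grade, a monotone response curve Q_thrombus(R_T) tabulated
from forward stroke simulations over a resistance grid; inverting it at
the measured flow yields the segment resistance, from which follow the
effective Darcy permeability kappa = mu L / (A (R_T - R_vessel)), the
pressure drop over the clot and the infarct volume (both read from the
same simulations).

A synthetic measurement generator stands in for the study cohort (the
clinical measurement table is not published); it samples physiologically
plausible ranges and is reproducible under a seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .config import COLLATERAL_GRADE_PROBABILITY, ModelConfig
from .thrombus import Thrombus, stroke_run, vessel_resistance
from .infarct import infarct_from_results
from .pipeline import healthy_run
from .units import PA_TO_MMHG

logger = logging.getLogger(__name__)


@dataclass
class PatientMeasurement:
    """Dynamic-CTA thrombus measurements for one patient."""

    patient_id: str
    transit_time_s: float
    void_fraction: float
    length_mm: float
    lumen_area_mm2: float
    collateral_grade: str = "moderate"

    def __post_init__(self) -> None:
        if self.transit_time_s <= 0:
            raise ValueError("transit_time_s must be > 0")
        if not 0.0 <= self.void_fraction <= 1.0:
            raise ValueError("void_fraction must be in [0, 1]")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")
        if self.lumen_area_mm2 <= 0:
            raise ValueError("lumen_area_mm2 must be > 0")


@dataclass
class PatientEstimate:
    """Model-derived quantities for one patient."""

    patient_id: str
    collateral_grade: str
    flow_ml_s: float
    resistance_Pa_s_ml: float
    dp_mmHg: float
    kappa_mm2: float
    infarct_ml: float
    warnings: list[str] = field(default_factory=list)


def flow_from_measurement(m: PatientMeasurement) -> float:
    """Q = eps * A * L / dt, converted mm^3/s -> ml/s (eps = 0 gives 0)."""
    return m.void_fraction * m.lumen_area_mm2 * m.length_mm / m.transit_time_s * 1e-3


@dataclass
class ResponseCurve:
    """Tabulated mean model response vs thrombus segment resistance.

    Monotone-decreasing flow interpolant, invertible on its range; dp and
    infarct volume share the same resistance grid.  ``occluded_*`` hold the
    fully-occluding (R_T = inf) limit for the eps = 0 branch.
    """

    collateral_probability: float
    R_T_Pa_s_ml: np.ndarray
    Q_thrombus_ml_s: np.ndarray
    dp_Pa: np.ndarray
    infarct_ml: np.ndarray
    occluded_dp_Pa: float
    occluded_infarct_ml: float
    host_r0_mm: float
    host_vessel_resistance_Pa_s_ml: float
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        x = np.log10(self.R_T_Pa_s_ml)
        if np.any(np.diff(x) <= 0):
            raise ValueError("resistance grid must be strictly increasing")
        q = self.Q_thrombus_ml_s
        tol = 1e-9 * max(abs(q).max(), 1e-30)
        if np.any(np.diff(q) > tol):
            raise ValueError("tabulated flow is not monotone decreasing in "
                             "resistance beyond noise tolerance")
        # strictify tiny non-monotone noise so the inverse is well defined
        self.Q_thrombus_ml_s = np.minimum.accumulate(q)
        self._q_of_logR = PchipInterpolator(x, self.Q_thrombus_ml_s)
        self._dp_of_logR = PchipInterpolator(x, self.dp_Pa)
        self._iv_of_logR = PchipInterpolator(x, self.infarct_ml)

    def flow_at(self, R_T_Pa_s_ml) -> np.ndarray | float:
        return self._q_of_logR(np.log10(R_T_Pa_s_ml))

    def dp_at(self, R_T_Pa_s_ml) -> float:
        return float(self._dp_of_logR(math.log10(R_T_Pa_s_ml)))

    def infarct_at(self, R_T_Pa_s_ml) -> float:
        return float(self._iv_of_logR(math.log10(R_T_Pa_s_ml)))

    @property
    def flow_range(self) -> tuple[float, float]:
        return float(self.Q_thrombus_ml_s[-1]), float(self.Q_thrombus_ml_s[0])


def build_response_curve(config: ModelConfig, collateral_probability: float,
                         resistance_grid_Pa_s_ml, seeds,
                         length_mm: float = 10.0) -> ResponseCurve:
    """Forward-simulate the flow/pressure/infarct response over a resistance grid.

    One network realization (healthy baseline) per seed; for each grid
    resistance the clot permeability reproducing exactly that total
    segment resistance is applied and the stroke simulated.  Results are
    averaged over seeds.  The grid must be sorted and span at least four
    decades.
    """
    grid = np.asarray(sorted(resistance_grid_Pa_s_ml), dtype=float)
    if np.log10(grid[-1] / grid[0]) < 4.0:
        raise ValueError("resistance grid must span at least 4 decades")
    q_acc, dp_acc, iv_acc = [], [], []
    occ_dp, occ_iv = [], []
    host_r0 = None
    r_vessel = None
    for seed in seeds:
        cfg = replace(config, network=replace(
            config.network, collateral_probability=collateral_probability,
            seed=int(seed)))
        healthy = healthy_run(cfg)
        host_id = healthy.network.meta["thrombus_vessel"]
        host = healthy.network.vessel_by_id(host_id)
        host_r0 = host.r0_mm
        area = math.pi * host_r0 ** 2
        r_vessel = vessel_resistance(host_r0, host.length_mm, cfg.solver)
        qs, dps, ivs = [], [], []
        for r_t in grid:
            kappa = permeability_from_resistance(
                r_t, length_mm, area, cfg.solver.viscosity_Pa_s, r_vessel)
            outcome = stroke_run(healthy, Thrombus(host_id, length_mm, kappa))
            iv, _ = infarct_from_results(healthy.result, outcome.result,
                                         cfg.infarct)
            qs.append(outcome.Q_thrombus_ml_s)
            dps.append(outcome.dp_Pa)
            ivs.append(iv)
        occluded = stroke_run(healthy, Thrombus(host_id, length_mm, 0.0))
        iv_occ, _ = infarct_from_results(healthy.result, occluded.result,
                                         cfg.infarct)
        occ_dp.append(occluded.dp_Pa)
        occ_iv.append(iv_occ)
        q_acc.append(qs)
        dp_acc.append(dps)
        iv_acc.append(ivs)
    return ResponseCurve(
        collateral_probability=collateral_probability,
        R_T_Pa_s_ml=grid,
        Q_thrombus_ml_s=np.mean(q_acc, axis=0),
        dp_Pa=np.mean(dp_acc, axis=0),
        infarct_ml=np.mean(iv_acc, axis=0),
        occluded_dp_Pa=float(np.mean(occ_dp)),
        occluded_infarct_ml=float(np.mean(occ_iv)),
        host_r0_mm=float(host_r0),
        host_vessel_resistance_Pa_s_ml=float(r_vessel),
        seeds=tuple(int(s) for s in seeds),
    )


def invert_to_resistance(Q_measured_ml_s: float, curve: ResponseCurve,
                         clamp: bool = False) -> float:
    """Segment resistance whose simulated thrombus flow equals the measurement.

    Monotone root-find on the tabulated interpolant.  Out-of-range
    measurements raise, or with ``clamp=True`` are clamped to the curve's
    range with a warning (a flow above the healthy branch clamps to the
    lowest grid resistance).
    """
    q_lo, q_hi = curve.flow_range
    q = Q_measured_ml_s
    if not q_lo <= q <= q_hi:
        if not clamp:
            raise ValueError(
                f"measured flow {q:.3g} ml/s outside the simulated response "
                f"range [{q_lo:.3g}, {q_hi:.3g}] ml/s")
        warnings.warn(f"measured flow {q:.3g} ml/s clamped to the response "
                      f"range [{q_lo:.3g}, {q_hi:.3g}]", stacklevel=2)
        q = min(max(q, q_lo), q_hi)
    x = np.log10(curve.R_T_Pa_s_ml)
    if q == q_hi:
        return float(curve.R_T_Pa_s_ml[0])
    if q == q_lo:
        return float(curve.R_T_Pa_s_ml[-1])
    log_r = brentq(lambda t: float(curve._q_of_logR(t)) - q, x[0], x[-1],
                   xtol=1e-13, rtol=8.9e-16)
    return float(10.0 ** log_r)


def permeability_from_resistance(R_T_Pa_s_ml: float, length_mm: float,
                                 area_mm2: float, viscosity_Pa_s: float,
                                 R_vessel_Pa_s_ml: float = 0.0) -> float:
    """kappa = mu L / (A (R_T - R_vessel)) in mm^2 (inverse of the Darcy law).

    R_T at or below the bare vessel resistance returns the
    infinite-permeability sentinel with a warning.
    """
    if R_T_Pa_s_ml <= R_vessel_Pa_s_ml:
        warnings.warn("segment resistance does not exceed the vessel "
                      "resistance; permeability unbounded", stacklevel=2)
        return math.inf
    r_darcy_si = (R_T_Pa_s_ml - R_vessel_Pa_s_ml) * 1e6  # Pa s/m^3
    kappa_m2 = viscosity_Pa_s * (length_mm * 1e-3) / ((area_mm2 * 1e-6) * r_darcy_si)
    return kappa_m2 * 1e6  # m^2 -> mm^2


def estimate_patient(m: PatientMeasurement, curve: ResponseCurve,
                     viscosity_Pa_s: float = 3.5e-3) -> PatientEstimate:
    """Chain measurement -> flow -> resistance -> permeability/dp/infarct."""
    warns: list[str] = []
    q = flow_from_measurement(m)
    if m.void_fraction == 0.0 or q <= curve.flow_range[0]:
        # fully impervious branch: the occluding simulation supplies dp and IV
        return PatientEstimate(m.patient_id, m.collateral_grade, q, math.inf,
                               curve.occluded_dp_Pa * PA_TO_MMHG, 0.0,
                               curve.occluded_infarct_ml,
                               warns + (["flow at or below occluding branch"]
                                        if m.void_fraction > 0 else []))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        r_t = invert_to_resistance(q, curve, clamp=True)
        kappa = permeability_from_resistance(
            r_t, m.length_mm, m.lumen_area_mm2, viscosity_Pa_s,
            curve.host_vessel_resistance_Pa_s_ml)
    warns.extend(str(w.message) for w in caught)
    return PatientEstimate(m.patient_id, m.collateral_grade, q, r_t,
                           curve.dp_at(r_t) * PA_TO_MMHG, kappa,
                           curve.infarct_at(r_t), warns)


def estimate_cohort(measurements, curves: dict[str, ResponseCurve],
                    viscosity_Pa_s: float = 3.5e-3) -> pd.DataFrame:
    """Estimate every patient against the response curve of their grade."""
    rows = []
    for m in measurements:
        if m.collateral_grade not in curves:
            raise KeyError(f"no response curve for grade {m.collateral_grade!r}")
        e = estimate_patient(m, curves[m.collateral_grade], viscosity_Pa_s)
        rows.append({
            "patient_id": e.patient_id,
            "collateral_grade": e.collateral_grade,
            "flow_ml_s": e.flow_ml_s,
            "resistance_Pa_s_ml": e.resistance_Pa_s_ml,
            "dp_mmHg": e.dp_mmHg,
            "kappa_mm2": e.kappa_mm2,
            "infarct_ml": e.infarct_ml,
            "warnings": "; ".join(e.warnings),
        })
    return pd.DataFrame(rows)


#: default sampling ranges of the synthetic cohort generator
DEFAULT_COHORT_RANGES = {
    "transit_time_s": (1.0, 30.0),    # log-uniform
    "void_fraction": (0.0, 0.5),      # uniform
    "length_mm": (3.0, 28.0),         # uniform (clinically observed clot lengths)
    "lumen_area_mm2": (3.0, 8.0),     # uniform
}


def generate_synthetic_cohort(n: int, ranges: dict | None = None,
                              seed: int = 0) -> list[PatientMeasurement]:
    """Sample a synthetic patient cohort (stands in for unpublished data).

    Transit time is log-uniform; void fraction, clot length and lumen area
    uniform within their ranges.  Collateral grades are assigned uniformly
    at random.  Reproducible under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    r = {**DEFAULT_COHORT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    grades = list(COLLATERAL_GRADE_PROBABILITY)
    out = []
    for i in range(n):
        dt = float(np.exp(rng.uniform(*np.log(r["transit_time_s"]))))
        out.append(PatientMeasurement(
            patient_id=f"synthetic-{i:03d}",
            transit_time_s=dt,
            void_fraction=float(rng.uniform(*r["void_fraction"])),
            length_mm=float(rng.uniform(*r["length_mm"])),
            lumen_area_mm2=float(rng.uniform(*r["lumen_area_mm2"])),
            collateral_grade=grades[int(rng.integers(len(grades)))],
        ))
    return out


def read_measurements_csv(path: str | Path) -> list[PatientMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [PatientMeasurement(str(r.patient_id), float(r.transit_time_s),
                               float(r.void_fraction), float(r.length_mm),
                               float(r.lumen_area_mm2),
                               str(getattr(r, "collateral_grade", "moderate")))
            for r in df.itertuples()]


def write_measurements_csv(measurements, path: str | Path) -> None:
    # %.17g guarantees bit-exact float round-trips through the CSV
    pd.DataFrame([m.__dict__ for m in measurements]).to_csv(
        path, index=False, float_format="%.17g")
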