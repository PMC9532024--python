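"""Model configuration with physiological defaults.

The defaults encode the baseline parameter set of the model: inlet pressure
12 500 Pa and inlet flow 100 ml/s at the heart, venous outlet pressure
666 Pa, blood viscosity 3.5 mPa s, velocity-profile constant zeta = 9
(blunt profile), pial vessel radius 0.2 mm, length-radius ratio 10,
Murray exponent 3, brain volume 1390 ml, cerebral perfusion 12.5 ml/s,
autoregulation pressure limits 10-100 mmHg and an infarct threshold of a
40% fractional flow-rate drop.

Configuration files are YAML with dotted namespaces flattened into
sections (``network:``, ``solver:``, ``autoregulation:``, ``thrombus:``,
``infarct:``, ``inversion:``).  Unknown keys are an error; validation
reports every violated invariant at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .units import MMHG_TO_PA


class ConfigError(ValueError):
    """Raised when a configuration file is invalid; message lists all problems."""


@dataclass
class NetworkConfig:
    """Parameters of the synthetic vasculature generator."""

    surface_resolution: int = 3          # icosphere refinement level
    collateral_probability: float = 0.65  # fraction of crossing pial vessels kept
    length_radius_ratio: float = 10.0
    murray_exponent: float = 3.0
    pial_radius_mm: float = 0.2
    penetrating_length_mm: float = 2.5   # cortical thickness of the outlet stubs
    brain_volume_ml: float = 1390.0
    n_outlet_target: int | None = None   # overrides surface_resolution if set
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if not 0.0 <= self.collateral_probability <= 1.0:
            errs.append("network.collateral_probability must be in [0, 1]")
        if self.murray_exponent <= 0:
            errs.append("network.murray_exponent must be > 0")
        if self.pial_radius_mm <= 0:
            errs.append("network.pial_radius_mm must be > 0")
        if self.length_radius_ratio <= 0:
            errs.append("network.length_radius_ratio must be > 0")
        if self.surface_resolution < 1:
            errs.append("network.surface_resolution must be >= 1")
        if self.brain_volume_ml <= 0:
            errs.append("network.brain_volume_ml must be > 0")
        if self.penetrating_length_mm <= 0:
            errs.append("network.penetrating_length_mm must be > 0")
        return errs


@dataclass
class SolverConfig:
    """Parameters of the steady-state elastic network solver."""

    viscosity_Pa_s: float = 3.5e-3
    zeta: float = 9.0                    # 2 = parabolic (Poiseuille), 9 = blunt
    poisson: float = 0.5
    reference_pressure_Pa: float = 80.0 * MMHG_TO_PA   # diastolic
    inlet_pressure_Pa: float = 12_500.0
    outlet_pressure_Pa: float = 666.0
    inlet_flow_ml_s: float = 100.0
    young_modulus_Pa: float = 1.6e6      # all cerebral vessels
    pressure_tol: float = 1e-6
    bc_tol: float = 1e-6
    max_iterations: int = 200
    relaxation: float = 0.7              # under-relaxation of radius updates

    def validate(self) -> list[str]:
        errs = []
        if self.viscosity_Pa_s <= 0:
            errs.append("solver.viscosity_Pa_s must be > 0")
        if self.zeta < 0:
            errs.append("solver.zeta must be >= 0")
        if not 0.0 <= self.poisson < 1.0:
            errs.append("solver.poisson must be in [0, 1)")
        if self.inlet_pressure_Pa <= self.outlet_pressure_Pa:
            errs.append("solver.inlet_pressure_Pa must exceed solver.outlet_pressure_Pa")
        if self.pressure_tol <= 0 or self.bc_tol <= 0:
            errs.append("solver tolerances must be > 0")
        if not 0.0 < self.relaxation <= 1.0:
            errs.append("solver.relaxation must be in (0, 1]")
        if self.inlet_flow_ml_s <= 0:
            errs.append("solver.inlet_flow_ml_s must be > 0")
        if self.young_modulus_Pa <= 0:
            errs.append("solver.young_modulus_Pa must be > 0")
        return errs


@dataclass
class AutoregulationConfig:
    """Outlet-resistance autoregulation parameters."""

    Q_brain_ml_s: float = 12.5
    P_low_mmHg: float = 10.0
    P_upp_mmHg: float = 100.0
    tol: float = 1e-6
    max_iter: int = 500
    relaxation: float = 1.0              # damping on resistance updates

    def validate(self) -> list[str]:
        errs = []
        if self.Q_brain_ml_s <= 0:
            errs.append("autoregulation.Q_brain_ml_s must be > 0")
        if not self.P_low_mmHg < self.P_upp_mmHg:
            errs.append("autoregulation.P_low_mmHg must be < autoregulation.P_upp_mmHg")
        if self.tol <= 0:
            errs.append("autoregulation.tol must be > 0")
        if not 0.0 < self.relaxation <= 1.0:
            errs.append("autoregulation.relaxation must be in (0, 1]")
        return errs


@dataclass
class ThrombusConfig:
    """Default thrombus placement (first M1 segment of the right MCA)."""

    vessel_id: int | None = None         # None -> the generator's R-MCA root
    length_mm: float = 10.0
    permeability_mm2: float | None = 0.0  # 0 or None = fully occluding

    def validate(self) -> list[str]:
        errs = []
        if self.length_mm <= 0:
            errs.append("thrombus.length_mm must be > 0")
        if self.permeability_mm2 is not None and self.permeability_mm2 < 0:
            errs.append("thrombus.permeability_mm2 must be >= 0")
        return errs


@dataclass
class InfarctConfig:
    """Perfusion-threshold infarct estimation parameters."""

    threshold: float = 0.4               # fractional flow-rate drop
    brain_volume_ml: float = 1390.0

    def validate(self) -> list[str]:
        errs = []
        if not 0.0 < self.threshold < 1.0:
            errs.append("infarct.threshold must be in (0, 1)")
        if self.brain_volume_ml <= 0:
            errs.append("infarct.brain_volume_ml must be > 0")
        return errs


@dataclass
class InversionConfig:
    """Measurement-inversion parameters (response curves per collateral grade)."""

    n_seeds: int = 5                     # network realizations averaged per curve
    resistance_grid_decades: tuple[float, float] = (3.0, 10.0)  # log10 Pa s/ml
    n_grid: int = 13

    def validate(self) -> list[str]:
        errs = []
        if self.n_seeds < 1:
            errs.append("inversion.n_seeds must be >= 1")
        lo, hi = self.resistance_grid_decades
        if not hi - lo >= 4.0:
            errs.append("inversion.resistance_grid_decades must span >= 4 decades")
        if self.n_grid < 4:
            errs.append("inversion.n_grid must be >= 4")
        return errs


#: clinical collateral grades and their calibrated inclusion probabilities
COLLATERAL_GRADE_PROBABILITY = {
    "absent": 0.05,
    "poor": 0.25,
    "moderate": 0.50,
    "good": 0.65,
}


@dataclass
class ModelConfig:
    """Full configuration: one section per pipeline stage."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    autoregulation: AutoregulationConfig = field(default_factory=AutoregulationConfig)
    thrombus: ThrombusConfig = field(default_factory=ThrombusConfig)
    infarct: InfarctConfig = field(default_factory=InfarctConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)

    def validate(self) -> None:
        errs: list[str] = []
        for section in dataclasses.fields(self):
            errs.extend(getattr(self, section.name).validate())
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["inversion"]["resistance_grid_decades"] = list(
            d["inversion"]["resistance_grid_decades"]
        )
        return d


_SECTIONS = {
    "network": NetworkConfig,
    "solver": SolverConfig,
    "autoregulation": AutoregulationConfig,
    "thrombus": ThrombusConfig,
    "infarct": InfarctConfig,
    "inversion": InversionConfig,
}


def config_from_dict(data: dict[str, Any] | None) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a (possibly partial) dict.

    Missing keys fall back to the physiological defaults; unknown sections
    or keys raise :class:`ConfigError` naming every offender.
    """
    data = data or {}
    errs: list[str] = []
    unknown_sections = set(data) - set(_SECTIONS)
    if unknown_sections:
        errs.append(f"unknown config sections: {sorted(unknown_sections)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section_data = dict(data.get(name) or {})
        valid_keys = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section_data) - valid_keys
        if unknown:
            errs.append(f"unknown keys in section '{name}': {sorted(unknown)}")
            for k in unknown:
                section_data.pop(k)
        if name == "inversion" and "resistance_grid_decades" in section_data:
            section_data["resistance_grid_decades"] = tuple(
                section_data["resistance_grid_decades"]
            )
        kwargs[name] = cls(**section_data)
    if errs:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
    cfg = ModelConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the full default parameter set.
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML (round-trips through :func:`load_config`)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
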