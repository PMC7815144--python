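"""Configuration schema, presets and built-in genotypes.

Run configurations are YAML (or JSON) documents validated against a strict
schema: unknown keys are rejected, and every omitted field falls back to the
standard parameterisation (the ``table1`` preset).  Units are fixed
throughout: concentrations mM, times min, volumes L, fluxes mM/min.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict

from glycoevo.engine import SimulationConfig
from glycoevo.environment import EnvironmentConfig, GlucoseSchedule
from glycoevo.kinetics import Genotype, KineticParameters
from glycoevo.physiology import REFERENCE_GENOTYPE, CostModel, PhysiologyParameters

__all__ = [
    "RunConfig",
    "load_config",
    "load_preset",
    "preset_names",
    "builtin_genotypes",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsSection(_Strict):
    """Kinetic constants; all concentrations mM."""

    KM_glc: float = 0.1
    KM_atp: float = 0.1
    Ki_atp: float = 3.0
    a_tot: float = 5.0
    KM_fbp: float = 1.0
    KM_adp: float = 0.1
    KM_p: float = 2.0
    Pi_vac_max: float = 10.0
    K_vac: float = 250.0
    m: float = 4.0

    def build(self) -> KineticParameters:
        return KineticParameters(**self.model_dump())


class CostSection(_Strict):
    """Expression-cost function (weights dimensionless, c_u in mM)."""

    variant: Literal["power_sum", "power_of_sum"] = "power_sum"
    w_up: float = 1.0
    w_lo: float = 1.0
    w_atp: float = 1.0
    w_p: float = 1.0
    n: float = 4.0
    c_u: float = 1.0
    vatp_e_ref: float = 5.0

    def build(self) -> CostModel:
        return CostModel(**self.model_dump())


class PhysiologySection(_Strict):
    """Growth/health calibration (fluxes mM/min, times min, V_c in L)."""

    vatp_m: float = 0.0
    tau_g: float = 90.0
    tau_d: float = 420.0
    vatp_ref_balanced: float = 12.7
    vatp_ref_imbalanced: float = 0.46
    vatp_e_ref: float = 5.0
    V_c: float = 3.35e-15

    def build(self) -> PhysiologyParameters:
        return PhysiologyParameters(**self.model_dump())


class ScheduleSection(_Strict):
    """Glucose supply schedule (concentrations mM, durations min)."""

    kind: Literal["constant", "square_wave", "pulse_train"] = "constant"
    glc0_on: float = 2.0
    glc0_off: float = 0.01
    T_on: float = 20.0
    T_off_mean: float = 20.0
    T_off_cv: float = 0.0
    t_origin: float = 0.0

    def build(self) -> GlucoseSchedule:
        return GlucoseSchedule(**self.model_dump())


class EnvironmentSection(_Strict):
    """Chamber model (V_ch in L, D and d in 1/min)."""

    mode: Literal["chemostat", "ncg"] = "ncg"
    V_ch: float = 1e-8
    D: float = 5.0
    d: float = 1e-6
    schedule: ScheduleSection = ScheduleSection()

    def build(self) -> EnvironmentConfig:
        data = self.model_dump()
        data["schedule"] = self.schedule.build()
        return EnvironmentConfig(**data)


class SimulationSection(_Strict):
    """Protocol parameters (times min)."""

    N0: int = 10000
    N_star: int = 10000
    N_tr: int = 100
    t_s: float = 0.0
    t_ms: float = 10000.0
    t_me: float = 500000.0
    t_e: float = 800000.0
    dt_p: float = 5.0
    dt_s: float = 1.0
    mu: float = 1e-2
    sigma: float = 0.1
    atol_c: float = 1e-5
    rtol_c: float = 1e-5
    atol_v: float = 0.01e-15
    rtol_v: float = 0.0
    atol_h: float = 1e-2
    rtol_h: float = 0.0
    init_genotype_span: float = 10.0
    track_start: float | None = None
    mutate_both_daughters: bool = True

    def build(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class RunConfig(_Strict):
    """Complete, strictly validated run configuration."""

    seed: int = 0
    reference_genotype: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 0.3)
    kinetics: KineticsSection = KineticsSection()
    cost: CostSection = CostSection()
    physiology: PhysiologySection = PhysiologySection()
    environment: EnvironmentSection = EnvironmentSection()
    simulation: SimulationSection = SimulationSection()

    def build(self) -> dict[str, Any]:
        """Resolve to runtime objects."""
        return {
            "seed": self.seed,
            "reference": Genotype(*self.reference_genotype),
            "kinetics": self.kinetics.build(),
            "cost": self.cost.build(),
            "physiology": self.physiology.build(),
            "environment": self.environment.build(),
            "simulation": self.simulation.build(self.seed),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys raise a validation error naming the offending fields; an
    empty document resolves to the full default (``table1``) parameterisation.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)


def _preset_dir():
    return importlib.resources.files("glycoevo") / "presets"


def preset_names() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str, **overrides: Any) -> RunConfig:
    """Load a shipped preset by name, optionally overriding top-level keys."""
    res = _preset_dir() / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    data = yaml.safe_load(text) or {}
    data.update(overrides)
    return RunConfig(**data)


def builtin_genotypes() -> dict[str, Genotype]:
    """Named genotypes: the reference parameterisation and the balanced- and
    imbalanced-competitor pair used in coexistence experiments."""
    return {
        "reference": REFERENCE_GENOTYPE,
        "BC": Genotype(9.90956, 6.97388, 6.14105, 1.27357),
        "IC": Genotype(10.92211, 5.65143, 4.82003, 2.07099),
    }
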