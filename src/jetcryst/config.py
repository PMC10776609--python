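"""Run configuration: schema, validation, defaults.

A run is described by a YAML file validated against the pydantic models
below.  Unknown keys are rejected (with the offending key named), defaults
are explicit, and the fully-resolved configuration is echoed next to the
results so every run is reproducible from its output directory alone.

Interface units mirror the published operating tables (m/s, kg/s, K,
weight percent, micrometre-scale grids given in metres); internals are
strict SI.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["RunConfig", "load_config", "config_to_dict", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Model):
    """Crystal-size grid: default 30 classes of 2 um spanning 0-60 um."""

    r_min: float = 0.0
    r_max: float = 60e-6
    n_classes: int = 30

    @model_validator(mode="after")
    def _check(self):
        if self.r_min < 0 or self.r_max <= self.r_min:
            raise ValueError("grid span must satisfy 0 <= r_min < r_max")
        if self.n_classes < 3:
            raise ValueError("n_classes must be >= 3")
        return self


class SolutionInletConfig(_Model):
    """Lovastatin-methanol feed stream.

    Exactly one of ``velocity`` (m/s) or ``mass_flow`` (kg/s) must be given.
    The solute loading is set either by the supersaturation ratio
    ``S_inlet`` relative to the stream's own (w_as, T) solubility, or
    directly by ``C`` (kg solute per kg solvents).
    """

    velocity: Optional[float] = 1.5
    mass_flow: Optional[float] = None
    S_inlet: Optional[float] = 8.8
    C: Optional[float] = None
    w_as: float = 0.0
    T: float = 298.15

    @model_validator(mode="after")
    def _check(self):
        if (self.velocity is None) == (self.mass_flow is None):
            raise ValueError(
                "inlet must set exactly one of 'velocity' or 'mass_flow'")
        if (self.S_inlet is None) == (self.C is None):
            raise ValueError("inlet must set exactly one of 'S_inlet' or 'C'")
        if not 0.0 <= self.w_as <= 100.0:
            raise ValueError("w_as must lie in [0, 100]")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        return self


class AntiSolventInletConfig(_Model):
    """Pure-water anti-solvent stream."""

    velocity: Optional[float] = 1.5
    mass_flow: Optional[float] = None
    T: float = 298.15

    @model_validator(mode="after")
    def _check(self):
        if (self.velocity is None) == (self.mass_flow is None):
            raise ValueError(
                "inlet must set exactly one of 'velocity' or 'mass_flow'")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        return self


class PremixedInletConfig(_Model):
    """Optional already-mixed feed (enters environment 3 directly).

    Used for single-stream studies such as the imposed-kinetics MSMPR
    configuration.
    """

    velocity: Optional[float] = None
    mass_flow: Optional[float] = None
    volumetric_flow: Optional[float] = None  # m^3/s, convenience
    C: float = 0.0
    w_as: float = 50.0
    T: float = 298.15
    xi: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        given = [x is not None
                 for x in (self.velocity, self.mass_flow, self.volumetric_flow)]
        if sum(given) != 1:
            raise ValueError("premixed inlet must set exactly one of "
                             "'velocity', 'mass_flow' or 'volumetric_flow'")
        return self


class InletsConfig(_Model):
    solution: Optional[SolutionInletConfig] = Field(
        default_factory=SolutionInletConfig)
    anti_solvent: Optional[AntiSolventInletConfig] = Field(
        default_factory=AntiSolventInletConfig)
    premixed: Optional[PremixedInletConfig] = None

    @model_validator(mode="after")
    def _check(self):
        if self.premixed is None:
            if self.solution is None or self.anti_solvent is None:
                raise ValueError(
                    "need solution and anti_solvent inlets (or a premixed inlet)")
        return self


class TurbulenceConfig(_Model):
    """Per-compartment turbulence: prescribed eps/k list, or scaled from the
    inlet velocity as eps/k = coefficient * v_char / d_jet with a geometric
    decay factor downstream of the impingement compartment."""

    mode: Literal["scaled", "prescribed"] = "scaled"
    coefficient: float = 10.0
    decay: float = 0.5
    eps_over_k: Optional[list[float]] = None
    k: Optional[list[float]] = None
    eps: Optional[list[float]] = None
    D_t: float = 1e-4

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "prescribed":
            if self.eps_over_k is None and (self.k is None or self.eps is None):
                raise ValueError(
                    "prescribed turbulence needs 'eps_over_k' or both 'k' and 'eps'")
        return self


class NetworkConfig(_Model):
    """Compartment representation of the crystallizer's active mixing zone.

    ``total_volume`` defaults to the impingement-region scale of a
    millimetre-nozzle jet device (0.5 mm^3); see docs/methods.md for why the
    active zone, not the full chamber, is the modelled control volume.
    """

    total_volume: float = 5e-10           # m^3
    n_chambers: int = 4                   # compartments downstream of impingement
    impingement_fraction: float = 0.2     # volume fraction of the first cell
    nozzle_area: float = 3.3339e-7        # m^2 per inlet (d_jet ~ 0.65 mm)
    turbulence: TurbulenceConfig = Field(default_factory=TurbulenceConfig)

    @model_validator(mode="after")
    def _check(self):
        if self.total_volume <= 0 or self.nozzle_area <= 0:
            raise ValueError("volumes and areas must be positive")
        if self.n_chambers < 0:
            raise ValueError("n_chambers must be >= 0")
        if not 0.0 < self.impingement_fraction <= 1.0:
            raise ValueError("impingement_fraction must lie in (0, 1]")
        return self

    @property
    def d_jet(self) -> float:
        return math.sqrt(4.0 * self.nozzle_area / math.pi)


class KineticsConfig(_Model):
    """Kinetic laws: live lovastatin correlations or imposed constant rates."""

    mode: Literal["lovastatin", "constant"] = "lovastatin"
    branch_mode: Literal["continuity_restored", "as_printed"] = "continuity_restored"
    B0: float = 0.0          # imposed nucleation rate, #/(m^3 s) (constant mode)
    G0: float = 0.0          # imposed growth rate, m/s (constant mode)
    k_v: float = math.pi / 6.0
    rho_crystal: float = 1273.0


class EnergyConfig(_Model):
    """Enthalpy-balance parameters.

    ``dH_mix`` (J per kg of solvents engulfed into the mixed environment) is
    calibrated, not derived: its default reproduces the ~+10 K adiabatic
    temperature rise of the equal-mass-flow operating point.  ``dH_crys``
    defaults to the enthalpy-of-fusion scale and contributes negligibly.
    """

    dH_mix: float = -3.4e4
    dH_crys: float = -1.0e5
    cp: float = 3000.0
    adiabatic: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.cp <= 0:
            raise ValueError("cp must be positive")
        return self


class SolverConfig(_Model):
    method: Literal["RK45", "RK23", "LSODA", "BDF"] = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    steady_tol: float = 1e-6
    max_residence_times: float = 120.0
    chunk_residence_fraction: float = 1.0
    t_end: Optional[float] = None   # fixed-horizon run instead of steady search

    @model_validator(mode="after")
    def _check(self):
        if self.rtol <= 0 or self.atol < 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")
        return self


class RunConfig(_Model):
    template: Literal["mixed_cell", "pfr_chain", "impinging_jet"] = "impinging_jet"
    grid: GridConfig = Field(default_factory=GridConfig)
    inlets: InletsConfig = Field(default_factory=InletsConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    energy: EnergyConfig = Field(default_factory=EnergyConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    initial_fill: Literal["anti_solvent", "premixed_saturated"] = "anti_solvent"
    seed: int = 0


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(x) for x in e["loc"]) or "<root>"
        lines.append(f"{loc}: {e['msg']}")
    return "invalid configuration:\n  " + "\n  ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def config_to_dict(cfg: RunConfig) -> dict:
    """Fully-resolved configuration (all defaults explicit)."""
    return cfg.model_dump(mode="json")
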