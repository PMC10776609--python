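"""Crystallization kinetics for lovastatin in methanol/water blends.

Water is the anti-solvent: adding it to a lovastatin-methanol solution
collapses the solubility and drives nucleation and growth.  This module
collects the closed-form correlations — solubility ``C*(w_as, T)``,
supersaturation ratio ``S = C/C*``, primary (homogeneous + heterogeneous)
nucleation rate ``B(S)`` and linear growth rate ``G(S)`` — together with the
mass-balance bookkeeping needed to blend a solution stream with an
anti-solvent stream.

Conventions
-----------
* ``C`` — solute concentration, kg lovastatin per kg of solvents
  (methanol + water, solute excluded).
* ``w_as`` — anti-solvent (water) weight percent on a solute-free solvents
  basis, 0–100.
* The nucleation and growth correlations are isothermal fits at 23 °C; they
  are applied at all temperatures (no temperature correction is available),
  and can be replaced wholesale through the run configuration.

The published solubility correlation switches from a cubic to a linear form
in ``w_as``.  The linear coefficients as printed produce an ~85x jump at the
switch point; restoring continuity requires only a sign/exponent fix on the
slope (-1.7884e-2 instead of +1.7884), which is the default here
(``branch_mode="continuity_restored"``).  The literal printed form remains
available via ``branch_mode="as_printed"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "MixtureState",
    "KineticRates",
    "Stream",
    "solubility",
    "supersaturation",
    "nucleation_rate",
    "growth_rate",
    "kinetic_rates",
    "mix_streams",
    "solution_density",
]

#: w_as value (weight %) where the solubility correlation changes branch.
W_AS_BRANCH = 45.67

#: Reference temperature of the solubility correlation, K.
T_REF = 296.0

# Nucleation / growth correlation constants (23 C fits).
_B_HOM_PREF = 6.97e14     # #/(m^3 s)
_B_HOM_EXP = 15.8
_B_HET_PREF = 2.18e8      # #/(m^3 s)
_B_HET_EXP = 0.994
_G_PREF = 8.33e-30        # m/s
_G_LNS_COEF = 2.46e3
_G_POWER = 6.7


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical properties of the water/methanol/lovastatin system.

    ``k_v`` (crystal volume shape factor) is not reported for lovastatin;
    the volume-equivalent-sphere value pi/6 is used by default and only
    rescales mass-basis outputs.
    """

    rho_water: float = 997.1          # kg/m^3
    rho_methanol: float = 782.0       # kg/m^3
    rho_crystal: float = 1273.0       # kg/m^3
    nu_water: float = 8.976e-7        # m^2/s
    nu_methanol: float = 6.87e-7      # m^2/s
    T_ref: float = T_REF              # K
    k_v: float = math.pi / 6.0        # -
    dH_mix: float = -3.4e4            # J per kg of solvents mixed (calibrated)
    dH_crys: float = -1.0e5           # J per kg crystal
    cp: float = 3000.0                # J/(kg K)


@dataclass
class MixtureState:
    """Liquid-phase composition with derived solubility and supersaturation.

    S = C / C_star; S = 0 when C = 0.
    """

    C: float          # kg solute / kg solvents
    w_as: float       # anti-solvent weight percent, 0-100
    T: float          # K
    C_star: float     # kg/kg solvents
    S: float          # dimensionless


@dataclass
class KineticRates:
    """Nucleation and growth rates at one supersaturation state."""

    B_hom: float      # #/(m^3 s)
    B_het: float      # #/(m^3 s)
    B: float          # #/(m^3 s), B_hom + B_het
    G: float          # m/s


@dataclass
class Stream:
    """A feed stream: total mass flow plus liquid composition."""

    mass_flow: float  # kg/s (solution + solute)
    C: float          # kg solute / kg solvents
    w_as: float       # weight percent water in solvents
    T: float          # K


def _check_domain(w_as, T) -> None:
    w = np.asarray(w_as, dtype=float)
    t = np.asarray(T, dtype=float)
    if np.any(w < 0.0) or np.any(w > 100.0):
        raise ValueError(f"w_as must lie in [0, 100], got {w_as!r}")
    if np.any(t <= 0.0):
        raise ValueError(f"temperature must be positive, got {T!r}")


def solubility(w_as, T, branch_mode: str = "continuity_restored"):
    """Lovastatin solubility, kg per kg of solvents.

    C*(w_as, T) = 0.001 exp(15.45763 (1 - 1/theta)) * p(w_as) with
    theta = T / 296 K.  ``p`` is cubic in ``w_as`` up to 45.67 wt% water and
    linear above; ``branch_mode`` selects the literal printed linear
    coefficients (``"as_printed"``) or the continuity-restoring ones
    (``"continuity_restored"``, default).

    Accepts scalars or arrays; returns a float for scalar input.
    """
    _check_domain(w_as, T)
    if branch_mode not in ("continuity_restored", "as_printed"):
        raise ValueError(f"unknown branch_mode {branch_mode!r}")
    w = np.asarray(w_as, dtype=float)
    t = np.asarray(T, dtype=float)
    theta = t / T_REF
    temp_factor = np.exp(15.45763 * (1.0 - 1.0 / theta))
    cubic = (-2.7455e-4 * w**3 + 3.3716e-2 * w**2 - 1.6704 * w + 33.089)
    if branch_mode == "as_printed":
        upper = 1.7884 * w + 1.7888
    else:
        upper = -1.7884e-2 * w + 1.7888
    poly = np.where(w <= W_AS_BRANCH, cubic, upper)
    out = 0.001 * temp_factor * poly
    if np.isscalar(w_as) and np.isscalar(T):
        return float(out)
    return out


def supersaturation(C, w_as, T, branch_mode: str = "continuity_restored") -> MixtureState:
    """Build a :class:`MixtureState` with solubility and S = C/C* filled in."""
    if np.any(np.asarray(C, dtype=float) < 0.0):
        raise ValueError(f"solute concentration must be non-negative, got {C!r}")
    c_star = solubility(w_as, T, branch_mode=branch_mode)
    S = np.asarray(C, dtype=float) / np.asarray(c_star, dtype=float)
    if np.isscalar(C):
        S = float(S)
    return MixtureState(C=C, w_as=w_as, T=T, C_star=c_star, S=S)


def _rates_from_lnS(pref, coef, lnS):
    return pref * np.exp(-coef / lnS**2)


def nucleation_rate(S) -> KineticRates:
    """Total primary nucleation rate B = B_hom + B_het, #/(m^3 s).

    Both contributions vanish in the limit S -> 1+ (ln S -> 0+, the
    exponential goes to exp(-inf)); S <= 1 therefore returns exactly zero.
    """
    s = np.asarray(S, dtype=float)
    if np.any(s < 0.0):
        raise ValueError(f"supersaturation ratio must be non-negative, got {S!r}")
    lnS = np.log(np.where(s > 1.0, s, np.e))  # placeholder where inactive
    active = s > 1.0
    b_hom = np.where(active, _rates_from_lnS(_B_HOM_PREF, _B_HOM_EXP, lnS), 0.0)
    b_het = np.where(active, _rates_from_lnS(_B_HET_PREF, _B_HET_EXP, lnS), 0.0)
    if np.isscalar(S):
        b_hom, b_het = float(b_hom), float(b_het)
        return KineticRates(B_hom=b_hom, B_het=b_het, B=b_hom + b_het, G=0.0)
    return KineticRates(B_hom=b_hom, B_het=b_het, B=b_hom + b_het, G=np.zeros_like(b_hom))


def growth_rate(S):
    """Size-independent linear growth rate G(S), m/s; zero for S <= 1."""
    s = np.asarray(S, dtype=float)
    if np.any(s < 0.0):
        raise ValueError(f"supersaturation ratio must be non-negative, got {S!r}")
    lnS = np.log(np.where(s > 1.0, s, np.e))
    g = np.where(s > 1.0, _G_PREF * (_G_LNS_COEF * lnS) ** _G_POWER, 0.0)
    if np.isscalar(S):
        return float(g)
    return g


def kinetic_rates(S) -> KineticRates:
    """Nucleation and growth rates in one call."""
    rates = nucleation_rate(S)
    rates.G = growth_rate(S)
    return rates


def solution_density(C: float, w_as: float, constants: PhysicalConstants | None = None) -> float:
    """Stream density from ideal (volume-additive) mixing, kg/m^3.

    Basis: 1 kg of solvents carrying ``C`` kg of dissolved lovastatin.
    """
    const = constants or PhysicalConstants()
    _check_domain(w_as, 300.0)
    x_w = w_as / 100.0
    volume = ((1.0 - x_w) / const.rho_methanol
              + x_w / const.rho_water
              + C / const.rho_crystal)
    return (1.0 + C) / volume


def mix_streams(stream_a: Stream, stream_b: Stream,
                branch_mode: str = "continuity_restored") -> tuple[MixtureState, float]:
    """Blend two streams; returns the mixed state and the solvents mass flow.

    Mass-conserving: solute, methanol and water are summed independently.
    Temperature is the mass-flow-weighted average (equal specific heats).
    """
    if stream_a.mass_flow < 0 or stream_b.mass_flow < 0:
        raise ValueError("stream mass flows must be non-negative")
    total = stream_a.mass_flow + stream_b.mass_flow
    if total <= 0:
        raise ValueError("at least one stream must have positive mass flow")
    solute = methanol = water = 0.0
    t_num = 0.0
    for s in (stream_a, stream_b):
        solvents = s.mass_flow / (1.0 + s.C)
        solute += solvents * s.C
        water += solvents * s.w_as / 100.0
        methanol += solvents * (1.0 - s.w_as / 100.0)
        t_num += s.mass_flow * s.T
    solvents_flow = methanol + water
    C = solute / solvents_flow
    w_as = 100.0 * water / solvents_flow
    T = t_num / total
    return supersaturation(C, w_as, T, branch_mode=branch_mode), solvents_flow
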