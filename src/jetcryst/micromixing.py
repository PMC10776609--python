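"""Three-environment presumed-PDF micromixing model.

Each fluid element is attributed to one of three environments:

1. unmixed solution feed (lovastatin in methanol), mixture fraction 1;
2. unmixed anti-solvent feed (water), mixture fraction 0;
3. the mixed environment, where the species actually meet and
   crystallization takes place.

The model transports the environment probabilities P1, P2, P3 and the
probability-weighted composition of environment 3, ``s3 = P3 * Phi3``.
Environments 1 and 2 keep the fixed compositions of their feeds.
Engulfment of unmixed fluid into environment 3 proceeds at a rate gamma
set by the scalar dissipation rate eps_xi = C_phi <xi'^2> eps/k
(C_phi = 2), where <xi'^2> is the mixture-fraction variance implied by the
three-delta PDF.  The source terms conserve total probability and leave
the cell-mean of every conserved scalar unchanged; spurious-dissipation
corrections (gamma_s terms) are active only where a resolved spatial
gradient of <xi>_3 exists (1-D compartment chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentState",
    "TurbulenceInput",
    "MicromixSources",
    "mixture_fraction_variance",
    "scalar_dissipation",
    "micromixing_sources",
    "mean_composition",
    "env3_mixture_fraction",
]

C_PHI = 2.0
#: gamma denominator below which the cell is treated as fully engulfed.
DEGENERATE_TOL = 1e-14


@dataclass
class TurbulenceInput:
    """Prescribed turbulence quantities of a compartment."""

    k: float                 # turbulent kinetic energy, m^2/s^2
    eps: float               # dissipation rate, m^2/s^3
    D_t: float = 0.0         # turbulent diffusivity, m^2/s
    grad_xi3: float = 0.0    # |grad <xi>_3|, 1/m (0 in 0-D compartments)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("turbulent kinetic energy k must be positive")
        if self.eps < 0 or self.D_t < 0:
            raise ValueError("eps and D_t must be non-negative")

    @classmethod
    def from_ratio(cls, eps_over_k: float, D_t: float = 0.0,
                   grad_xi3: float = 0.0) -> "TurbulenceInput":
        """Build from the ratio eps/k (1/s), which is all the model needs."""
        return cls(k=1.0, eps=eps_over_k, D_t=D_t, grad_xi3=grad_xi3)

    @property
    def eps_over_k(self) -> float:
        return self.eps / self.k


@dataclass
class EnvironmentState:
    """Probabilities and environment-3 weighted composition of one cell."""

    P: np.ndarray                       # (P1, P2, P3)
    s3: np.ndarray                      # weighted composition of env 3
    s3_xi: float                        # weighted mixture fraction P3*<xi>_3
    phi1: np.ndarray                    # fixed composition of env 1
    phi2: np.ndarray                    # fixed composition of env 2

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.s3 = np.asarray(self.s3, dtype=float)
        self.phi1 = np.asarray(self.phi1, dtype=float)
        self.phi2 = np.asarray(self.phi2, dtype=float)

    @property
    def xi3(self) -> float:
        return env3_mixture_fraction(self.s3_xi, float(self.P[2]))

    @property
    def xi_var(self) -> float:
        return mixture_fraction_variance(self.P, self.xi3)


def env3_mixture_fraction(s3_xi: float, P3: float) -> float:
    """Mean mixture fraction of environment 3, clamped to [0, 1].

    <xi>_3 is maintained as the transported weighted scalar P3*<xi>_3
    divided by P3.  With no mixed fluid (P3 = 0) the value is undefined and
    the symmetric default 0.5 is returned.
    """
    if P3 <= 0.0:
        return 0.5
    return float(np.clip(s3_xi / P3, 0.0, 1.0))


def mixture_fraction_variance(P, xi3: float) -> float:
    """Mixture-fraction variance of the three-delta PDF.

    <xi'^2> = P1(1-P1) - 2 P1 P3 <xi>_3 + P3(1-P3) <xi>_3^2
    """
    P1, _, P3 = np.asarray(P, dtype=float)
    return float(P1 * (1.0 - P1) - 2.0 * P1 * P3 * xi3
                 + P3 * (1.0 - P3) * xi3**2)


def scalar_dissipation(xi_var: float, turb: TurbulenceInput) -> float:
    """eps_xi = C_phi <xi'^2> eps/k, the variance decay rate (1/s)."""
    return C_PHI * xi_var * turb.eps_over_k


@dataclass
class MicromixSources:
    """Rates of change produced by micromixing in one cell.

    ``e1 = gamma P1(1-P1)`` and ``e2 = gamma P2(1-P2)`` are the engulfment
    rates from environments 1 and 2; the weighted-composition source is
    ``ds3 = e1*phi1 + e2*phi2 + ms_factor*(phi1 + phi2)`` for any species
    vector.  ``gs`` are the spurious-dissipation probability corrections
    (zero in 0-D compartments).
    """

    dP1: float
    dP2: float
    dP3: float
    e1: float
    e2: float
    gamma: float
    gamma_s: float
    gs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ms_factor: float = 0.0

    @property
    def dP(self) -> np.ndarray:
        return np.array([self.dP1, self.dP2, self.dP3])

    def ds3(self, phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray:
        phi1 = np.asarray(phi1, dtype=float)
        phi2 = np.asarray(phi2, dtype=float)
        return self.e1 * phi1 + self.e2 * phi2 + self.ms_factor * (phi1 + phi2)


def micromixing_sources(P, xi3: float, turb: TurbulenceInput) -> MicromixSources:
    """Probability and weighted-composition sources of the 3-environment model.

    gamma = eps_xi / [P1(1-P1)(1 - <xi>_3^2) + P2(1-P2) <xi>_3^2]

    dP1 = -gamma P1(1-P1) + gamma_s P3
    dP2 = -gamma P2(1-P2) + gamma_s P3
    dP3 =  gamma [P1(1-P1) + P2(1-P2)] - 2 gamma_s P3

    with gamma_s = [2 D_t / ((1-<xi>_3)^2 + <xi>_3^2)] |grad <xi>_3|^2.
    When the gamma denominator is degenerate (nothing left to engulf) all
    sources are zero.
    """
    P1, P2, P3 = np.asarray(P, dtype=float)
    xi3 = float(np.clip(xi3, 0.0, 1.0))
    a = P1 * (1.0 - P1)
    b = P2 * (1.0 - P2)
    denom = a * (1.0 - xi3**2) + b * xi3**2
    if denom < DEGENERATE_TOL:
        return MicromixSources(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    xi_var = mixture_fraction_variance((P1, P2, P3), xi3)
    eps_xi = scalar_dissipation(max(xi_var, 0.0), turb)
    gamma = eps_xi / denom
    gamma_s = (2.0 * turb.D_t / ((1.0 - xi3) ** 2 + xi3**2)) * turb.grad_xi3**2
    e1 = gamma * a
    e2 = gamma * b
    gs = (gamma_s * P3, gamma_s * P3, -2.0 * gamma_s * P3)
    return MicromixSources(
        dP1=-e1 + gs[0],
        dP2=-e2 + gs[1],
        dP3=(e1 + e2) + gs[2],
        e1=e1, e2=e2, gamma=gamma, gamma_s=gamma_s, gs=gs,
        ms_factor=-gamma_s * P3,
    )


def mean_composition(env: EnvironmentState) -> np.ndarray:
    """Cell-mean species vector Phi = P1 phi1 + P2 phi2 + s3."""
    return env.P[0] * env.phi1 + env.P[1] * env.phi2 + env.s3
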