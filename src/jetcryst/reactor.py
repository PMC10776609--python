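"""Compartment-network crystallizer: couples mixing, kinetics, PBE, energy.

The 3-D turbulent flow field of the jet crystallizer is replaced by a
small network of well-mixed compartments with prescribed turbulence
quantities and balanced volumetric flows.  Within each compartment the
three-environment micromixing model decides how much of the fluid is
actually mixed; crystallization (nucleation + size-resolved growth via the
high-resolution PBE scheme) happens in the mixed environment only, at the
supersaturation of that environment's composition.  A single enthalpy
balance per compartment carries the heat of mixing and of crystallization.

State vector (per compartment): P1, P2, P3, the environment-3 weighted
mixture fraction, the environment-3 weighted species concentrations
(solute, methanol, water; kg per m^3 of suspension), the crystal number
densities f_j (environment-3 weighted, #/m^4), and temperature T (K).

The modelled control volume is the *active* impingement/mixing zone of the
jet device (mm^3 scale, millisecond residence), where supersaturation is
generated and crystals form; see docs/methods.md for the regime argument
behind that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import kinetics as kin
from . import micromixing as mm
from . import pbe
from .config import RunConfig

__all__ = [
    "Network",
    "InletStream",
    "CSDSummary",
    "ReactorResult",
    "SimulationError",
    "ConvergenceError",
    "build_network",
    "closed_cell_network",
    "assemble_rhs",
    "run",
    "outlet_summary",
    "parameter_sweep",
    "flow_audit",
]

# species indices in the composition vectors
SOLUTE, METHANOL, WATER = 0, 1, 2

# per-compartment state layout
_P1, _P2, _P3, _SXI, _SOL, _ME, _WA = range(7)
_F0 = 7  # first crystal class; T sits at _F0 + n


class SimulationError(RuntimeError):
    """Integration failed (solver error, NaN state, ...)."""


class ConvergenceError(SimulationError):
    """Steady state not reached within the allowed horizon."""


@dataclass
class InletStream:
    """A boundary feed attached to one compartment."""

    name: str
    Q: float                # m^3/s
    rho: float              # kg/m^3
    env: int                # 1 = solution, 2 = anti-solvent, 3 = premixed
    conc: np.ndarray        # (solute, methanol, water) kg per m^3 of stream
    T: float                # K
    xi: float               # mixture fraction carried by the stream
    target: int = 0         # compartment index it feeds

    @property
    def mass_flow(self) -> float:
        return self.Q * self.rho


@dataclass
class Network:
    """Flow-balanced compartment network plus all model parameters."""

    volumes: np.ndarray             # (nc,), m^3
    Q: np.ndarray                   # (nc, nc), Q[i, j] = flow i -> j, m^3/s
    Q_outlet: np.ndarray            # (nc,), boundary outflow per compartment
    inlets: list[InletStream]
    eps_over_k: np.ndarray          # (nc,), 1/s
    D_t: np.ndarray                 # (nc,), m^2/s
    positions: np.ndarray | None    # (nc,), m; None for 0-D compartments
    grid: pbe.SizeGrid
    phi1: np.ndarray                # solution-feed composition, kg/m^3
    phi2: np.ndarray                # anti-solvent composition, kg/m^3
    constants: kin.PhysicalConstants
    kinetics_mode: str = "lovastatin"
    branch_mode: str = "continuity_restored"
    B0: float = 0.0
    G0: float = 0.0
    dH_mix: float = -3.4e4
    dH_crys: float = -1.0e5
    cp: float = 3000.0
    adiabatic: bool = True
    template: str = "custom"

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.Q_outlet = np.asarray(self.Q_outlet, dtype=float)
        self.phi1 = np.asarray(self.phi1, dtype=float)
        self.phi2 = np.asarray(self.phi2, dtype=float)
        self.eps_over_k = np.asarray(self.eps_over_k, dtype=float)
        self.D_t = np.asarray(self.D_t, dtype=float)
        self._check_balance()

    # -- layout helpers -------------------------------------------------
    @property
    def nc(self) -> int:
        return self.volumes.size

    @property
    def n_classes(self) -> int:
        return self.grid.n

    @property
    def nv(self) -> int:
        return self.grid.n + 8

    @property
    def i_T(self) -> int:
        return _F0 + self.grid.n

    @property
    def f_slice(self) -> slice:
        return slice(_F0, _F0 + self.grid.n)

    @property
    def outlet_comp(self) -> int:
        return int(np.argmax(self.Q_outlet))

    @property
    def total_flow(self) -> float:
        return float(self.Q_outlet.sum())

    @property
    def residence_time(self) -> float:
        if self.total_flow <= 0:
            return math.inf
        return float(self.volumes.sum() / self.total_flow)

    @property
    def rho_ref(self) -> float:
        m = sum(i.mass_flow for i in self.inlets)
        q = sum(i.Q for i in self.inlets)
        if q <= 0:
            return self.constants.rho_water
        return m / q

    def _check_balance(self) -> None:
        q_in = self.Q.sum(axis=0).copy()
        for inlet in self.inlets:
            q_in[inlet.target] += inlet.Q
        q_out = self.Q.sum(axis=1) + self.Q_outlet
        scale = max(q_in.max(), q_out.max(), 1e-300)
        if np.any(np.abs(q_in - q_out) > 1e-12 * scale):
            raise ValueError("compartment network is not flow balanced")

    # -- state construction ---------------------------------------------
    def inlet_state(self, inlet: InletStream) -> np.ndarray:
        """State vector carried into the network by a boundary stream."""
        x = np.zeros(self.nv)
        if inlet.env == 1:
            x[_P1] = 1.0
        elif inlet.env == 2:
            x[_P2] = 1.0
        elif inlet.env == 3:
            x[_P3] = 1.0
            x[_SXI] = inlet.xi
            x[[_SOL, _ME, _WA]] = inlet.conc
        else:
            raise ValueError(f"unknown environment {inlet.env}")
        x[self.i_T] = inlet.T
        return x

    def initial_state(self, fill: str = "anti_solvent") -> np.ndarray:
        """Network state at t = 0.

        ``anti_solvent``: compartments start filled with unmixed water.
        ``premixed_saturated``: start from the flow-weighted blend of the
        feeds with the solute trimmed to saturation (shortens transients).
        """
        y = np.zeros((self.nc, self.nv))
        T0 = (np.mean([i.T for i in self.inlets]) if self.inlets else 298.15)
        if fill == "anti_solvent":
            y[:, _P2] = 1.0
        elif fill == "premixed_saturated":
            q = sum(i.Q for i in self.inlets)
            conc = sum(i.Q * i.conc for i in self.inlets) / q
            solv = conc[METHANOL] + conc[WATER]
            w = 100.0 * conc[WATER] / solv if solv > 0 else 100.0
            c_star = kin.solubility(w, T0, branch_mode=self.branch_mode)
            y[:, _P3] = 1.0
            y[:, _SXI] = 0.5
            y[:, _SOL] = min(conc[SOLUTE], c_star * solv)
            y[:, _ME] = conc[METHANOL]
            y[:, _WA] = conc[WATER]
        else:
            raise ValueError(f"unknown initial fill {fill!r}")
        y[:, self.i_T] = T0
        return y.ravel()


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _chain_flows(nc: int, inlets: list[InletStream]) -> tuple[np.ndarray, np.ndarray]:
    """All inlets feed compartment 0; flow passes down the chain and out."""
    q_total = sum(i.Q for i in inlets)
    Q = np.zeros((nc, nc))
    for i in range(nc - 1):
        Q[i, i + 1] = q_total
    Q_outlet = np.zeros(nc)
    Q_outlet[-1] = q_total
    return Q, Q_outlet


def _solution_stream(cfg: RunConfig) -> InletStream:
    sc = cfg.inlets.solution
    if sc.C is not None:
        C = sc.C
    else:
        C = sc.S_inlet * kin.solubility(sc.w_as, sc.T,
                                        branch_mode=cfg.kinetics.branch_mode)
    rho = kin.solution_density(C, sc.w_as)
    if sc.velocity is not None:
        Q = sc.velocity * cfg.network.nozzle_area
    else:
        Q = sc.mass_flow / rho
    solv_frac = 1.0 / (1.0 + C)
    conc = rho * np.array([C * solv_frac,
                           (1.0 - sc.w_as / 100.0) * solv_frac,
                           (sc.w_as / 100.0) * solv_frac])
    return InletStream("solution", Q=Q, rho=rho, env=1, conc=conc, T=sc.T, xi=1.0)


def _anti_solvent_stream(cfg: RunConfig, constants: kin.PhysicalConstants) -> InletStream:
    ac = cfg.inlets.anti_solvent
    rho = constants.rho_water
    if ac.velocity is not None:
        Q = ac.velocity * cfg.network.nozzle_area
    else:
        Q = ac.mass_flow / rho
    conc = np.array([0.0, 0.0, rho])
    return InletStream("anti_solvent", Q=Q, rho=rho, env=2, conc=conc, T=ac.T, xi=0.0)


def _premixed_stream(cfg: RunConfig) -> InletStream:
    pc = cfg.inlets.premixed
    rho = kin.solution_density(pc.C, pc.w_as)
    if pc.volumetric_flow is not None:
        Q = pc.volumetric_flow
    elif pc.velocity is not None:
        Q = pc.velocity * cfg.network.nozzle_area
    else:
        Q = pc.mass_flow / rho
    solv_frac = 1.0 / (1.0 + pc.C)
    conc = rho * np.array([pc.C * solv_frac,
                           (1.0 - pc.w_as / 100.0) * solv_frac,
                           (pc.w_as / 100.0) * solv_frac])
    return InletStream("premixed", Q=Q, rho=rho, env=3, conc=conc, T=pc.T, xi=pc.xi)


def build_network(cfg: RunConfig) -> Network:
    """Instantiate the compartment network named by the configuration.

    Templates: ``mixed_cell`` (one compartment), ``pfr_chain`` (equal-volume
    series with resolved 1-D mixture-fraction gradients) and
    ``impinging_jet`` (impingement compartment + chamber chain).  Inlet
    volumetric flows come from velocity x nozzle area or mass flow / stream
    density.
    """
    constants = kin.PhysicalConstants(
        k_v=cfg.kinetics.k_v, rho_crystal=cfg.kinetics.rho_crystal,
        dH_mix=cfg.energy.dH_mix, dH_crys=cfg.energy.dH_crys, cp=cfg.energy.cp)
    inlets: list[InletStream] = []
    if cfg.inlets.premixed is not None:
        inlets.append(_premixed_stream(cfg))
    if cfg.inlets.solution is not None and cfg.inlets.premixed is None:
        inlets.append(_solution_stream(cfg))
    if cfg.inlets.anti_solvent is not None and cfg.inlets.premixed is None:
        inlets.append(_anti_solvent_stream(cfg, constants))
    if not inlets:
        raise ValueError("network needs at least one inlet")

    net_cfg = cfg.network
    V = net_cfg.total_volume
    if cfg.template == "mixed_cell":
        volumes = np.array([V])
        positions = None
    elif cfg.template == "pfr_chain":
        nc = max(net_cfg.n_chambers, 1)
        volumes = np.full(nc, V / nc)
        length = V / (2.0 * net_cfg.nozzle_area)
        positions = (np.arange(nc) + 0.5) * (length / nc)
    elif cfg.template == "impinging_jet":
        nch = net_cfg.n_chambers
        v_imp = net_cfg.impingement_fraction * V
        volumes = np.concatenate([[v_imp],
                                  np.full(nch, (V - v_imp) / nch) if nch else []])
        positions = None
    else:  # pragma: no cover - pydantic restricts templates
        raise ValueError(f"unknown template {cfg.template!r}")

    nc = volumes.size
    Q, Q_outlet = _chain_flows(nc, inlets)

    turb = net_cfg.turbulence
    if turb.mode == "prescribed":
        if turb.eps_over_k is not None:
            eok = np.asarray(turb.eps_over_k, dtype=float)
        else:
            eok = np.asarray(turb.eps, dtype=float) / np.asarray(turb.k, dtype=float)
        if eok.size == 1:
            eok = np.full(nc, float(eok))
        if eok.size != nc:
            raise ValueError(
                f"prescribed turbulence needs {nc} values, got {eok.size}")
    else:
        v_char = float(np.mean([i.Q / net_cfg.nozzle_area for i in inlets]))
        base = turb.coefficient * v_char / net_cfg.d_jet
        eok = base * turb.decay ** np.arange(nc)

    phi1 = next((i.conc for i in inlets if i.env == 1), np.zeros(3))
    phi2 = next((i.conc for i in inlets if i.env == 2),
                np.array([0.0, 0.0, constants.rho_water]))

    return Network(
        volumes=volumes, Q=Q, Q_outlet=Q_outlet, inlets=inlets,
        eps_over_k=eok, D_t=np.full(nc, turb.D_t), positions=positions,
        grid=pbe.make_grid(cfg.grid.r_min, cfg.grid.r_max, cfg.grid.n_classes),
        phi1=phi1, phi2=phi2, constants=constants,
        kinetics_mode=cfg.kinetics.mode, branch_mode=cfg.kinetics.branch_mode,
        B0=cfg.kinetics.B0, G0=cfg.kinetics.G0,
        dH_mix=cfg.energy.dH_mix, dH_crys=cfg.energy.dH_crys,
        cp=cfg.energy.cp, adiabatic=cfg.energy.adiabatic,
        template=cfg.template,
    )


def closed_cell_network(grid: pbe.SizeGrid, eps_over_k: float = 100.0,
                        D_t: float = 0.0,
                        phi1: np.ndarray | None = None,
                        phi2: np.ndarray | None = None,
                        constants: kin.PhysicalConstants | None = None,
                        kinetics_mode: str = "lovastatin",
                        B0: float = 0.0, G0: float = 0.0,
                        dH_mix: float = -3.4e4, dH_crys: float = -1.0e5,
                        cp: float = 3000.0, volume: float = 1e-6) -> Network:
    """A single compartment with no through-flow, for conservation studies."""
    constants = constants or kin.PhysicalConstants()
    if phi1 is None:
        C = 0.3255
        rho = kin.solution_density(C, 0.0, constants)
        phi1 = rho * np.array([C / (1 + C), 1.0 / (1 + C), 0.0])
    if phi2 is None:
        phi2 = np.array([0.0, 0.0, constants.rho_water])
    return Network(
        volumes=np.array([volume]), Q=np.zeros((1, 1)), Q_outlet=np.zeros(1),
        inlets=[], eps_over_k=np.array([eps_over_k]), D_t=np.array([D_t]),
        positions=None, grid=grid, phi1=phi1, phi2=phi2, constants=constants,
        kinetics_mode=kinetics_mode, B0=B0, G0=G0,
        dH_mix=dH_mix, dH_crys=dH_crys, cp=cp, template="closed_cell",
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _kinetics_of_state(net: Network, Y: np.ndarray):
    """Supersaturation and rates per compartment from the env-3 composition."""
    sol = np.clip(Y[:, _SOL], 0.0, None)
    me = np.clip(Y[:, _ME], 0.0, None)
    wa = np.clip(Y[:, _WA], 0.0, None)
    T = np.clip(Y[:, net.i_T], 200.0, None)
    solv = me + wa
    have = solv > 1e-9
    solv_safe = np.where(have, solv, 1.0)
    C3 = np.where(have, sol / solv_safe, 0.0)
    w_as = np.clip(100.0 * wa / solv_safe, 0.0, 100.0)
    if net.kinetics_mode == "constant":
        S = np.zeros(net.nc)
        B = np.full(net.nc, net.B0)
        G = np.full(net.nc, net.G0)
        return S, B, G
    c_star = kin.solubility(w_as, T, branch_mode=net.branch_mode)
    S = np.where(have, C3 / c_star, 0.0)
    B = kin.nucleation_rate(S).B
    G = kin.growth_rate(S)
    return S, B, G


def assemble_rhs(net: Network):
    """Build the time-derivative function dY/dt for the whole network."""
    nc, nv, n = net.nc, net.nv, net.n_classes
    fsl = net.f_slice
    iT = net.i_T
    dr = net.grid.dr
    mw = pbe.mass_weights(net.grid, net.constants.rho_crystal, net.constants.k_v)
    rho_cp = net.rho_ref * net.cp
    solv1 = net.phi1[METHANOL] + net.phi1[WATER]
    solv2 = net.phi2[METHANOL] + net.phi2[WATER]

    # flow operator: dY += Mflow @ Y + Sin
    Mflow = net.Q.T / net.volumes[:, None]
    np.fill_diagonal(Mflow, np.diag(Mflow)
                     - (net.Q.sum(axis=1) + net.Q_outlet) / net.volumes)
    Sin = np.zeros((nc, nv))
    for inlet in net.inlets:
        Sin[inlet.target] += inlet.Q / net.volumes[inlet.target] \
            * net.inlet_state(inlet)

    live = net.kinetics_mode == "lovastatin"

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        Y = y.reshape(nc, nv)
        dY = Mflow @ Y + Sin

        # --- micromixing -------------------------------------------------
        P1, P2, P3 = Y[:, _P1], Y[:, _P2], Y[:, _P3]
        xi3 = np.where(P3 > 1e-12, Y[:, _SXI] / np.where(P3 > 1e-12, P3, 1.0), 0.5)
        xi3 = np.clip(xi3, 0.0, 1.0)
        a = np.clip(P1 * (1.0 - P1), 0.0, None)
        b = np.clip(P2 * (1.0 - P2), 0.0, None)
        denom = a * (1.0 - xi3**2) + b * xi3**2
        active = denom >= mm.DEGENERATE_TOL
        xi_var = np.clip(P1 * (1.0 - P1) - 2.0 * P1 * P3 * xi3
                         + P3 * (1.0 - P3) * xi3**2, 0.0, None)
        gamma = np.where(active,
                         mm.C_PHI * xi_var * net.eps_over_k
                         / np.where(active, denom, 1.0), 0.0)
        e1 = gamma * a
        e2 = gamma * b
        if net.positions is not None and nc > 1:
            grad = np.gradient(xi3, net.positions)
            gamma_s = (2.0 * net.D_t / ((1.0 - xi3) ** 2 + xi3**2)) * grad**2
        else:
            gamma_s = np.zeros(nc)
        gsP3 = gamma_s * P3
        ms = -gsP3  # coefficient of (phi1 + phi2) in the s3 source
        dY[:, _P1] += -e1 + gsP3
        dY[:, _P2] += -e2 + gsP3
        dY[:, _P3] += (e1 + e2) - 2.0 * gsP3
        dY[:, _SXI] += e1 * 1.0 + ms * 1.0
        for sp, i_sp in ((SOLUTE, _SOL), (METHANOL, _ME), (WATER, _WA)):
            dY[:, i_sp] += (e1 * net.phi1[sp] + e2 * net.phi2[sp]
                            + ms * (net.phi1[sp] + net.phi2[sp]))

        # --- crystallization ---------------------------------------------
        S, B, G = _kinetics_of_state(net, Y)
        prod = np.zeros(nc)
        for i in range(nc):
            ddf = None
            g = G[i]
            if g > 0.0:
                ddf = pbe.growth_flux_divergence(
                    np.clip(Y[i, fsl], 0.0, None), g, net.grid, mode="growth")
            elif g < 0.0:
                ddf = pbe.growth_flux_divergence(
                    np.clip(Y[i, fsl], 0.0, None), -g, net.grid,
                    mode="dissolution")
            if B[i] > 0.0:
                if ddf is None:
                    ddf = np.zeros(n)
                ddf[0] += P3[i] * B[i] / dr
            if ddf is not None:
                dY[i, fsl] += ddf
                prod[i] = mw @ ddf
        if live:
            # solute sink closes the mass balance with the crystal phase
            dY[:, _SOL] -= prod

        # --- enthalpy ------------------------------------------------------
        if net.adiabatic:
            s3_solvent_rate = e1 * solv1 + e2 * solv2 + ms * (solv1 + solv2)
            sh = s3_solvent_rate * (-net.dH_mix) + prod * (-net.dH_crys)
            dY[:, iT] += sh / rho_cp

        return dY.ravel()

    return rhs


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

@dataclass
class ReactorResult:
    """Trajectory (chunk ends) and final state of a network simulation."""

    network: Network
    times: np.ndarray
    states: np.ndarray           # (n_times, nc*nv)
    converged: bool
    steady_residual: float
    negativity_clips: int = 0
    max_negativity: float = 0.0

    @property
    def y(self) -> np.ndarray:
        return self.states[-1]

    @property
    def Y(self) -> np.ndarray:
        return self.states[-1].reshape(self.network.nc, self.network.nv)


def _atol_vector(net: Network, atol: float) -> np.ndarray:
    a = np.zeros((net.nc, net.nv))
    a[:, :_SXI + 1] = atol
    a[:, _SOL:_WA + 1] = max(atol * net.rho_ref, atol)
    a[:, net.f_slice] = 1.0          # #/m^4 — negligible on any populated class
    a[:, net.i_T] = max(atol * 300.0, atol)
    return a.ravel()


_BLOCKS = ("probability", "composition", "crystals", "temperature")


def _block_change(net: Network, y_old: np.ndarray, y_new: np.ndarray) -> float:
    Yo = y_old.reshape(net.nc, net.nv)
    Yn = y_new.reshape(net.nc, net.nv)
    res = 0.0
    for sl, floor in ((slice(_P1, _SXI + 1), 1.0),
                      (slice(_SOL, _WA + 1), 1e-3 * net.rho_ref),
                      (net.f_slice, 1.0),
                      (slice(net.i_T, net.i_T + 1), 300.0)):
        scale = max(np.abs(Yn[:, sl]).max(initial=0.0), floor)
        res = max(res, np.abs(Yn[:, sl] - Yo[:, sl]).max(initial=0.0) / scale)
    return res


def run(net: Network, t_end: float | None = None, steady_tol: float = 1e-6,
        method: str = "RK45", rtol: float = 1e-8, atol: float = 1e-10,
        max_residence_times: float = 120.0,
        chunk_residence_fraction: float = 1.0,
        initial_fill: str = "anti_solvent",
        y0: np.ndarray | None = None) -> ReactorResult:
    """Integrate the network to a fixed horizon or to steady state.

    Steady state is declared when the largest block-relative state change
    over one residence time drops below ``steady_tol``.  Negative number
    densities produced by the (non-positivity-preserving) adaptive stepper
    are clipped at chunk boundaries and audited.  With ``t_end`` set the run
    is a plain transient to that horizon.
    """
    if y0 is None:
        y0 = net.initial_state(initial_fill)
    rhs = assemble_rhs(net)
    tau = net.residence_time
    if not math.isfinite(tau):
        if t_end is None:
            raise ValueError("closed network: a fixed t_end is required")
        tau = t_end
    chunk = chunk_residence_fraction * tau
    if t_end is not None:
        horizon = t_end
        steady_mode = False
    else:
        horizon = max_residence_times * tau
        steady_mode = True
    atol_vec = _atol_vector(net, atol)

    t = 0.0
    y = np.asarray(y0, dtype=float).copy()
    times = [0.0]
    states = [y.copy()]
    clips = 0
    max_neg = 0.0
    residual = math.inf
    converged = not steady_mode
    fsl = net.f_slice
    while t < horizon - 1e-12 * max(horizon, 1.0):
        t_next = min(t + chunk, horizon)
        sol = solve_ivp(rhs, (t, t_next), y, method=method,
                        rtol=rtol, atol=atol_vec)
        if not sol.success:
            raise SimulationError(f"integrator failed at t={t:g}: {sol.message}")
        y_new = sol.y[:, -1]
        if not np.all(np.isfinite(y_new)):
            raise SimulationError(f"non-finite state at t={t_next:g}")
        Yn = y_new.reshape(net.nc, net.nv)
        neg = Yn[:, fsl] < 0.0
        if np.any(neg):
            clips += int(neg.sum())
            max_neg = max(max_neg, float(-Yn[:, fsl].min()))
            Yn[:, fsl] = np.clip(Yn[:, fsl], 0.0, None)
        residual = _block_change(net, y, y_new) / chunk_residence_fraction
        y = y_new
        t = t_next
        times.append(t)
        states.append(y.copy())
        if steady_mode and residual < steady_tol:
            converged = True
            break
    if steady_mode and not converged:
        raise ConvergenceError(
            f"no steady state within {max_residence_times:g} residence times; "
            f"last block-relative change per residence time = {residual:.3e}")
    return ReactorResult(network=net, times=np.asarray(times),
                         states=np.asarray(states), converged=converged,
                         steady_residual=residual,
                         negativity_clips=clips, max_negativity=max_neg)


def run_config(cfg: RunConfig) -> ReactorResult:
    """Convenience: build the network and run it per the solver settings."""
    net = build_network(cfg)
    s = cfg.solver
    return run(net, t_end=s.t_end, steady_tol=s.steady_tol, method=s.method,
               rtol=s.rtol, atol=s.atol,
               max_residence_times=s.max_residence_times,
               chunk_residence_fraction=s.chunk_residence_fraction,
               initial_fill=cfg.initial_fill)


# ---------------------------------------------------------------------------
# summaries and sweeps
# ---------------------------------------------------------------------------

@dataclass
class CSDSummary:
    """Outlet-stream and network-average results of a run."""

    number_mean_um: float
    number_std_um: float
    mass_mean_um: float
    mass_std_um: float
    total_number_per_m3: float
    total_mass_kg_m3: float
    outlet_mass_flow_mg_s: float
    avg_S: float
    avg_B: float
    avg_G: float
    T_out_K: float
    P3_out: float
    top_class_mass_fraction: float
    converged: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def outlet_summary(result: ReactorResult) -> CSDSummary:
    """Condense a finished run into the published-table quantities."""
    net = result.network
    Y = result.Y
    i_out = net.outlet_comp
    f_out = np.clip(Y[i_out, net.f_slice], 0.0, None)
    stats = pbe.csd_summary(f_out, net.grid,
                            rho_c=net.constants.rho_crystal,
                            k_v=net.constants.k_v)
    f_w = pbe.number_to_mass(f_out, net.grid, net.constants.rho_crystal,
                             net.constants.k_v)
    total_mass = float(f_w.sum())
    top_frac = float(f_w[-1] / total_mass) if total_mass > 0 else 0.0
    q_out = float(net.Q_outlet[i_out])
    S, B, G = _kinetics_of_state(net, Y)
    w = net.volumes / net.volumes.sum()
    return CSDSummary(
        number_mean_um=stats.number_mean * 1e6,
        number_std_um=stats.number_std * 1e6,
        mass_mean_um=stats.mass_mean * 1e6,
        mass_std_um=stats.mass_std * 1e6,
        total_number_per_m3=stats.total_number,
        total_mass_kg_m3=total_mass,
        outlet_mass_flow_mg_s=q_out * total_mass * 1e6,
        avg_S=float(w @ S), avg_B=float(w @ B), avg_G=float(w @ G),
        T_out_K=float(Y[i_out, net.i_T]), P3_out=float(Y[i_out, _P3]),
        top_class_mass_fraction=top_frac, converged=result.converged,
    )


SWEEP_PARAMS = ("inlet_velocity", "inlet_supersaturation", "ms_ma_ratio",
                "n_classes", "dr")


def _apply_sweep_value(cfg: RunConfig, param: str, value) -> RunConfig:
    c = cfg.model_copy(deep=True)
    if param == "inlet_velocity":
        c.inlets.solution = c.inlets.solution.model_copy(
            update={"velocity": float(value), "mass_flow": None})
        c.inlets.anti_solvent = c.inlets.anti_solvent.model_copy(
            update={"velocity": float(value), "mass_flow": None})
    elif param == "inlet_supersaturation":
        c.inlets.solution = c.inlets.solution.model_copy(
            update={"S_inlet": float(value), "C": None})
    elif param == "ms_ma_ratio":
        ac = c.inlets.anti_solvent
        ma = ac.mass_flow
        if ma is None:
            ma = ac.velocity * c.network.nozzle_area * 997.1
            c.inlets.anti_solvent = ac.model_copy(
                update={"velocity": None, "mass_flow": ma})
        c.inlets.solution = c.inlets.solution.model_copy(
            update={"velocity": None, "mass_flow": float(value) * ma})
    elif param == "n_classes":
        c.grid.n_classes = int(value)
    elif param == "dr":
        span = c.grid.r_max - c.grid.r_min
        c.grid.n_classes = int(round(span / float(value)))
    else:
        raise ValueError(f"unknown sweep parameter {param!r}; "
                         f"choose from {SWEEP_PARAMS}")
    return c


def parameter_sweep(cfg: RunConfig, param: str, values) -> pd.DataFrame:
    """One steady run per value; returns a table of outlet summaries.

    Individual run failures are recorded in the ``error`` column and the
    sweep continues.
    """
    if param not in SWEEP_PARAMS:
        raise ValueError(f"unknown sweep parameter {param!r}; "
                         f"choose from {SWEEP_PARAMS}")
    rows = []
    for v in values:
        row = {param: v}
        try:
            result = run_config(_apply_sweep_value(cfg, param, v))
            row.update(outlet_summary(result).as_dict())
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - sweep must survive run failures
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

def flow_audit(result: ReactorResult) -> dict:
    """Steady-state closure diagnostics for an open network.

    Returns block-relative residuals of the species balances (inflow -
    outflow - net source), the enthalpy balance, and the probability norm,
    all normalised per residence time of throughput.
    """
    net = result.network
    Y = result.Y
    rhs = assemble_rhs(net)
    dY = rhs(result.times[-1], result.y).reshape(net.nc, net.nv)
    out = {}
    # probability normalisation
    p_err = np.abs(Y[:, _P1] + Y[:, _P2] + Y[:, _P3] - 1.0).max()
    out["probability_norm_error"] = float(p_err)
    # steady residuals: |dX/dt| * tau / scale (per second if no throughput)
    tau = net.residence_time
    if not math.isfinite(tau):
        tau = 1.0
    for name, sl, floor in (("solute", slice(_SOL, _SOL + 1), 1e-3),
                            ("solvents", slice(_ME, _WA + 1), 1e-3),
                            ("crystals", net.f_slice, 1.0),
                            ("temperature", slice(net.i_T, net.i_T + 1), 300.0)):
        scale = max(np.abs(Y[:, sl]).max(initial=0.0), floor)
        out[f"steady_residual_{name}"] = float(
            np.abs(dY[:, sl]).max(initial=0.0) * tau / scale)
    out["negativity_clips"] = result.negativity_clips
    out["max_negativity"] = result.max_negativity
    return out
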