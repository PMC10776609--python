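"""Analytic oracles, convergence studies and conservation audits.

Every numerical claim the package makes is checkable against a closed form
computed here, independently of the production flux/limiter code:

* constant-rate growth is exact translation, f(r, t) = f0(r - G t);
* the steady mixed-suspension mixed-product-removal (MSMPR) distribution
  with size-independent growth is f(r) = (B/G) exp(-r / (G tau));
* a deliberately first-order upwind integrator serves as a convergence
  control (observed order ~1) next to the high-resolution scheme (>= 2 on
  smooth data).

Fixture generation (initial size distributions + config snippets) is
deterministic given (name, parameters, seed).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pbe
from . import reactor as rx

__all__ = [
    "Fixture",
    "gaussian_profile",
    "step_profile",
    "class_averages",
    "analytic_advection",
    "msmpr_analytic",
    "upwind_advect",
    "convergence_order",
    "conservation_audit",
    "make_fixture",
    "verify_suite",
]


# ---------------------------------------------------------------------------
# profiles and oracles
# ---------------------------------------------------------------------------

def gaussian_profile(center: float, sigma: float, amplitude: float = 1.0):
    """Pointwise Gaussian number-density profile f0(r)."""
    def f(r):
        return amplitude * np.exp(-0.5 * ((np.asarray(r) - center) / sigma) ** 2)
    return f


def step_profile(lo: float, hi: float, amplitude: float = 1.0):
    """Top-hat profile: ``amplitude`` on [lo, hi), zero elsewhere."""
    def f(r):
        r = np.asarray(r, dtype=float)
        return np.where((r >= lo) & (r < hi), amplitude, 0.0)
    return f


def class_averages(profile, grid: pbe.SizeGrid, n_quad: int = 5) -> np.ndarray:
    """Exact-to-quadrature class averages of a pointwise profile."""
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    lo = grid.r_faces[:-1][:, None]
    hi = grid.r_faces[1:][:, None]
    r = 0.5 * (hi - lo) * nodes[None, :] + 0.5 * (hi + lo)
    vals = profile(r)
    return 0.5 * (vals * weights[None, :]).sum(axis=1)


def analytic_advection(profile, G: float, t: float):
    """Exact constant-rate growth solution: the translated profile.

    Returns a new pointwise profile r -> f0(r - G t), zero where the
    shifted argument falls below the original domain (nothing grows in
    from below size zero).
    """
    def f(r):
        r = np.asarray(r, dtype=float)
        shifted = r - G * t
        return np.where(shifted >= 0.0, profile(shifted), 0.0)
    return f


def msmpr_analytic(B: float, G: float, tau: float, grid: pbe.SizeGrid) -> np.ndarray:
    """Steady MSMPR size distribution as exact class averages.

    f(r) = (B/G) exp(-r / lambda), lambda = G tau.  The class average over
    [a, b] is (B/G) (lambda / (b - a)) (exp(-a/lambda) - exp(-b/lambda)).
    """
    if B <= 0 or G <= 0 or tau <= 0:
        raise ValueError("B, G and tau must be positive")
    lam = G * tau
    a = grid.r_faces[:-1]
    b = grid.r_faces[1:]
    return (B / G) * lam / (b - a) * (np.exp(-a / lam) - np.exp(-b / lam))


def upwind_advect(f0: np.ndarray, G: float, t_end: float, grid: pbe.SizeGrid,
                  cfl: float = 0.45) -> np.ndarray:
    """First-order upwind growth integrator — the convergence control.

    Deliberately independent of the high-resolution scheme: donor-cell
    fluxes, forward Euler.
    """
    f = np.asarray(f0, dtype=float).copy()
    if G <= 0 or t_end <= 0:
        return f
    dt = cfl * grid.dr / G
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    nu = G * dt / grid.dr
    for _ in range(n_steps):
        flux = f.copy()            # donor cell: H_{j+1/2} = G f_j
        f = f - nu * flux
        f[1:] += nu * flux[:-1]    # inflow from the class below; H_{1/2} = 0
    return f


def convergence_order(errors, drs) -> float:
    """Least-squares slope of log(error) vs log(dr)."""
    errors = np.asarray(errors, dtype=float)
    drs = np.asarray(drs, dtype=float)
    if errors.size < 3:
        raise ValueError("need at least three resolutions")
    if np.any(errors <= 0):
        raise ValueError("errors must be positive")
    slope = np.polyfit(np.log(drs), np.log(errors), 1)[0]
    return float(slope)


def advection_l1_error(profile, G: float, t_end: float, grid: pbe.SizeGrid,
                       integrator=None, theta: float = 1.5) -> float:
    """Relative L1 error of a growth-advection run against the exact shift."""
    f0 = class_averages(profile, grid)
    if integrator is None:
        f_num = pbe.advect(f0, G, t_end, grid, mode="growth", theta=theta,
                           outer_bc="outflow")
    else:
        f_num = integrator(f0, G, t_end, grid)
    f_ref = class_averages(analytic_advection(profile, G, t_end), grid)
    return float(np.abs(f_num - f_ref).sum() / max(np.abs(f_ref).sum(), 1e-300))


def advection_convergence(profile, G: float, t_end: float,
                          drs=(4e-6, 2e-6, 1e-6, 0.5e-6),
                          r_max: float = 60e-6, integrator=None,
                          theta: float = 1.5) -> tuple[float, np.ndarray]:
    """Observed L1 order of the scheme on constant-G advection."""
    errors = []
    for dr in drs:
        grid = pbe.make_grid(0.0, r_max, int(round(r_max / dr)))
        errors.append(advection_l1_error(profile, G, t_end, grid,
                                         integrator=integrator, theta=theta))
    return convergence_order(errors, drs), np.asarray(errors)


# ---------------------------------------------------------------------------
# conservation audit
# ---------------------------------------------------------------------------

def conservation_audit(result: rx.ReactorResult) -> dict:
    """Closure report for a finished run.

    For closed cells: drift of total probability, of the cell-mean of each
    species (micromixing must not move means), and of solute + crystal
    mass.  For open networks: the steady flow-balance residuals from
    :func:`jetcryst.reactor.flow_audit`.  All violations are relative.
    """
    net = result.network
    Y0 = result.states[0].reshape(net.nc, net.nv)
    Y1 = result.Y
    report = dict(rx.flow_audit(result))
    closed = net.total_flow == 0 and not net.inlets
    report["closed"] = closed
    if closed:
        V = net.volumes
        mw = pbe.mass_weights(net.grid, net.constants.rho_crystal,
                              net.constants.k_v)

        def mean_species(Y, sp, i_sp):
            return float(V @ (Y[:, 0] * net.phi1[sp] + Y[:, 1] * net.phi2[sp]
                              + Y[:, i_sp]))

        def crystal_mass(Y):
            return float(V @ (Y[:, net.f_slice] @ mw))

        sol0 = mean_species(Y0, rx.SOLUTE, rx._SOL)
        sol1 = mean_species(Y1, rx.SOLUTE, rx._SOL)
        cry0, cry1 = crystal_mass(Y0), crystal_mass(Y1)
        tot0, tot1 = sol0 + cry0, sol1 + cry1
        report["solute_plus_crystal_drift"] = abs(tot1 - tot0) / max(abs(tot0), 1e-300)
        for name, sp, i_sp in (("methanol", rx.METHANOL, rx._ME),
                               ("water", rx.WATER, rx._WA)):
            m0 = mean_species(Y0, sp, i_sp)
            m1 = mean_species(Y1, sp, i_sp)
            report[f"{name}_mean_drift"] = abs(m1 - m0) / max(abs(m0), 1e-300)
    return report


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_PROFILES = ("gaussian", "step", "empty", "msmpr_exponential")


@dataclass
class Fixture:
    """A reproducible initial size distribution + grid specification."""

    name: str
    profile: str
    params: dict
    grid_spec: dict = field(default_factory=lambda: dict(
        r_min=0.0, r_max=60e-6, n_classes=30))
    seed: int = 0
    perturbation: float = 0.0   # relative multiplicative noise, seeded

    def build(self) -> tuple[pbe.SizeGrid, np.ndarray]:
        grid = pbe.make_grid(self.grid_spec["r_min"], self.grid_spec["r_max"],
                             self.grid_spec["n_classes"])
        if self.profile == "empty":
            f = np.zeros(grid.n)
        elif self.profile == "gaussian":
            f = class_averages(gaussian_profile(**self.params), grid)
        elif self.profile == "step":
            f = class_averages(step_profile(**self.params), grid)
        elif self.profile == "msmpr_exponential":
            f = msmpr_analytic(self.params["B"], self.params["G"],
                               self.params["tau"], grid)
        else:
            raise ValueError(f"unknown profile {self.profile!r}; "
                             f"choose from {_PROFILES}")
        if self.perturbation > 0:
            rng = np.random.default_rng(self.seed)
            f = f * (1.0 + self.perturbation * rng.standard_normal(grid.n))
            f = np.clip(f, 0.0, None)
        return grid, f


def make_fixture(fixture: Fixture, outdir: str | Path) -> Path:
    """Write a fixture as a CSD CSV plus a matching YAML grid snippet.

    Byte-identical output for identical (name, parameters, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid, f = fixture.build()
    f_w = pbe.number_to_mass(f, grid, 1273.0, np.pi / 6.0)
    df = pd.DataFrame({
        "class_index": np.arange(grid.n),
        "r_lo_m": grid.r_faces[:-1],
        "r_hi_m": grid.r_faces[1:],
        "f_number_per_m4": f,
        "f_w_kg_per_m3": f_w,
    })
    csv_path = outdir / f"{fixture.name}.csv"
    df.to_csv(csv_path, index=False, float_format="%.12e")
    snippet = {"grid": dict(fixture.grid_spec),
               "fixture": {"name": fixture.name, "profile": fixture.profile,
                           "params": fixture.params, "seed": fixture.seed,
                           "perturbation": fixture.perturbation}}
    (outdir / f"{fixture.name}.yaml").write_text(
        yaml.safe_dump(snippet, sort_keys=True))
    return csv_path


def read_csd_csv(path: str | Path) -> tuple[pbe.SizeGrid, np.ndarray]:
    """Read a CSD table written by :func:`make_fixture`."""
    df = pd.read_csv(path)
    faces = np.append(df["r_lo_m"].to_numpy(), df["r_hi_m"].to_numpy()[-1])
    return pbe.SizeGrid(r_faces=faces), df["f_number_per_m4"].to_numpy()


# ---------------------------------------------------------------------------
# verify suites (used by the CLI)
# ---------------------------------------------------------------------------

def _suite_kinetics() -> dict:
    import math
    from . import kinetics as kin
    checks = {}
    checks["solubility_pure_methanol_296K"] = {
        "value": kin.solubility(0.0, 296.0), "expect": 0.033089, "tol": 1e-12}
    lo = kin.solubility(kin.W_AS_BRANCH, 296.0)
    hi = kin.solubility(np.nextafter(kin.W_AS_BRANCH, 100.0), 296.0)
    checks["solubility_branch_jump_rel"] = {
        "value": abs(hi - lo) / lo, "expect": 0.0, "tol": 5e-3}
    S = np.linspace(1.01, 20.0, 64)
    B = kin.nucleation_rate(S).B
    G = kin.growth_rate(S)
    checks["nucleation_monotone_in_S"] = {
        "value": float(np.all(np.diff(B) > 0)), "expect": 1.0, "tol": 0.0}
    checks["growth_monotone_in_S"] = {
        "value": float(np.all(np.diff(G) > 0)), "expect": 1.0, "tol": 0.0}
    return checks


#: Convergence-study profile: a Gaussian wide enough that even the
#: coarsest grid (4 um classes) resolves it; measured on a long size span
#: so the pulse stays clear of both boundaries.  Under-resolved profiles
#: measure pre-asymptotic behavior, not the scheme's order.
CONVERGENCE_PROFILE = dict(center=60e-6, sigma=16e-6, amplitude=1e15)
CONVERGENCE_SPAN = 180e-6
CONVERGENCE_SHIFT = 30e-6   # G * t


def smooth_convergence_order(drs=(4e-6, 2e-6, 1e-6, 0.5e-6),
                             theta: float = 1.5) -> tuple[float, np.ndarray]:
    """Observed L1 order of the scheme on the standard smooth study."""
    prof = gaussian_profile(**CONVERGENCE_PROFILE)
    return advection_convergence(prof, G=1e-6, t_end=CONVERGENCE_SHIFT / 1e-6,
                                 drs=drs, r_max=CONVERGENCE_SPAN, theta=theta)


def _suite_pbe(seed: int = 0) -> dict:
    checks = {}
    order, _ = smooth_convergence_order()
    checks["smooth_advection_l1_order"] = {
        "value": order, "expect": ">=1.8", "tol": None, "ok": order >= 1.8}
    rng = np.random.default_rng(seed)
    grid = pbe.make_grid(0.0, 60e-6, 30)
    violations = 0
    for _ in range(20):
        f0 = rng.random(grid.n)
        f1 = pbe.advect(f0, 1e-6, 5.0, grid, outer_bc="outflow")
        if f1.max() > f0.max() * (1 + 1e-12) or f1.min() < -1e-12 * f0.max():
            violations += 1
    checks["tvd_violations"] = {"value": violations, "expect": 0, "tol": 0,
                                "ok": violations == 0}
    return checks


def _suite_micromix() -> dict:
    from . import micromixing as mmix
    checks = {}
    turb = mmix.TurbulenceInput.from_ratio(1.0)
    src = mmix.micromixing_sources((0.25, 0.25, 0.5), 0.5, turb)
    checks["gamma_reference_state"] = {
        "value": src.gamma, "expect": 4.0 / 3.0, "tol": 1e-12}
    checks["probability_source_sum"] = {
        "value": abs(src.dP1 + src.dP2 + src.dP3), "expect": 0.0, "tol": 1e-15}
    return checks


def _suite_reactor() -> dict:
    checks = {}
    grid = pbe.make_grid(0.0, 60e-6, 60)
    net = msmpr_network(grid, B=1e12, G=1e-6, tau=10.0)
    res = rx.run(net, steady_tol=1e-8, rtol=1e-8, max_residence_times=400)
    f_num = res.Y[0, net.f_slice]
    f_ref = msmpr_analytic(1e12, 1e-6, 10.0, grid)
    l1 = float(np.abs(f_num - f_ref).sum() / np.abs(f_ref).sum())
    checks["msmpr_l1_error"] = {"value": l1, "expect": 0.0, "tol": 0.02,
                                "ok": l1 < 0.02}
    return checks


def msmpr_network(grid: pbe.SizeGrid, B: float, G: float, tau: float,
                   Q: float = 1e-6) -> rx.Network:
    """Single mixed cell, imposed constant kinetics, crystal-free feed."""
    from .config import RunConfig
    cfg = RunConfig.model_validate({
        "template": "mixed_cell",
        "grid": {"r_min": grid.r_faces[0], "r_max": grid.r_faces[-1],
                 "n_classes": grid.n},
        "inlets": {"solution": None, "anti_solvent": None,
                   "premixed": {"volumetric_flow": Q, "C": 0.0, "w_as": 50.0}},
        "network": {"total_volume": Q * tau},
        "kinetics": {"mode": "constant", "B0": B, "G0": G},
        "energy": {"adiabatic": False},
    })
    return rx.build_network(cfg)


SUITES = {
    "kinetics": _suite_kinetics,
    "pbe": _suite_pbe,
    "micromix": _suite_micromix,
    "reactor": _suite_reactor,
}


def verify_suite(name: str = "all", seed: int = 0) -> dict:
    """Run a named verification suite; returns a machine-readable report."""
    names = list(SUITES) if name == "all" else [name]
    report = {"suite": name, "checks": {}, "passed": True}
    for n in names:
        if n not in SUITES:
            raise ValueError(f"unknown suite {n!r}; choose from {list(SUITES)}")
        fn = SUITES[n]
        checks = fn(seed) if n == "pbe" else fn()
        for key, chk in checks.items():
            if "ok" not in chk:
                chk["ok"] = abs(chk["value"] - chk["expect"]) <= chk["tol"]
            report["checks"][f"{n}.{key}"] = chk
            report["passed"] = report["passed"] and bool(chk["ok"])
    return report
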