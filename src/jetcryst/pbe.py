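"""Size-discretized population balance: high-resolution finite-volume scheme.

The crystal size distribution is represented by cell-averaged number
densities ``f_j`` (#/m^4: per m^3 of suspension, per m of size) on a uniform
grid of size classes.  Growth (and dissolution) advect the distribution
along the size coordinate; the semi-discrete update is the conservative
flux difference

    df_j/dt = -(H_{j+1/2} - H_{j-1/2}) / dr

with upwind-biased MUSCL face reconstructions limited by the minmod
limiter (parameter ``theta`` in [1, 2], default 1.5).  The scheme is
second-order accurate on smooth profiles and total-variation-diminishing:
it creates no spurious oscillations and keeps non-negative data
non-negative under a CFL-limited SSP time step.

Nucleation enters as a delta source at the smallest resolvable size,
deposited entirely into the first class.  The number density is converted
to a per-class crystal mass density ``f_w,j`` (kg/m^3) through the exact
fourth-power face integral of ``rho_c k_v r^3 f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SizeGrid",
    "CrystalField",
    "FluxWorkspace",
    "make_grid",
    "minmod",
    "limited_slopes",
    "growth_flux_divergence",
    "nucleation_source",
    "number_to_mass",
    "mass_weights",
    "csd_summary",
    "CSDStats",
    "advect",
]


@dataclass(frozen=True)
class SizeGrid:
    """Uniform partition of the crystal-size coordinate into classes."""

    r_faces: np.ndarray   # class boundary radii, m, length N+1

    def __post_init__(self):
        faces = np.asarray(self.r_faces, dtype=float)
        object.__setattr__(self, "r_faces", faces)
        if faces.ndim != 1 or faces.size < 4:
            raise ValueError("grid needs at least 3 classes (4 faces)")
        widths = np.diff(faces)
        if np.any(widths <= 0):
            raise ValueError("grid faces must be strictly increasing")
        dr = widths.mean()
        if np.any(np.abs(widths - dr) > 1e-12 * dr):
            raise ValueError("grid must be uniform")

    @property
    def n(self) -> int:
        return self.r_faces.size - 1

    @property
    def dr(self) -> float:
        return float(self.r_faces[1] - self.r_faces[0])

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])


@dataclass
class CrystalField:
    """Per-class number density and (optionally) mass density."""

    f: np.ndarray                      # #/m^4
    f_w: np.ndarray | None = None      # kg/m^3


@dataclass
class FluxWorkspace:
    """Intermediate reconstruction data, exposed for inspection/testing."""

    slopes: np.ndarray        # limited derivatives (f_r)_j, #/m^5
    face_values: np.ndarray   # one-sided reconstruction used at each face
    H: np.ndarray             # face fluxes H_{j +/- 1/2}, #/(m^3 s)
    theta: float = 1.5


def make_grid(r_min: float, r_max: float, n: int) -> SizeGrid:
    """Uniform size grid with ``n`` classes spanning [r_min, r_max]."""
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    if r_max <= r_min:
        raise ValueError("r_max must exceed r_min")
    if n < 3:
        raise ValueError("need at least 3 classes")
    return SizeGrid(r_faces=np.linspace(r_min, r_max, n + 1))


def minmod(*candidates):
    """Minmod of the candidate slopes (elementwise for array input).

    Returns the minimum if all candidates are positive, the maximum if all
    are negative, and zero otherwise.
    """
    if not candidates:
        raise ValueError("minmod needs at least one candidate")
    stacked = np.stack([np.asarray(c, dtype=float) for c in candidates])
    all_pos = np.all(stacked > 0, axis=0)
    all_neg = np.all(stacked < 0, axis=0)
    out = np.where(all_pos, stacked.min(axis=0),
                   np.where(all_neg, stacked.max(axis=0), 0.0))
    if out.ndim == 0:
        return float(out)
    return out


def limited_slopes(f: np.ndarray, grid: SizeGrid, theta: float = 1.5) -> np.ndarray:
    """Minmod-limited per-class slopes (f_r)_j.

    Interior classes use minmod{theta*backward, centered, theta*forward}.
    The end classes use zero-gradient ghost values, which zeroes their
    limited slope: an unlimited one-sided slope at the inflow cell can
    reconstruct a face value larger than the cell holds and break
    positivity under the CFL step.
    """
    if not 1.0 <= theta <= 2.0:
        raise ValueError("theta must lie in [1, 2]")
    f = np.asarray(f, dtype=float)
    dr = grid.dr
    slopes = np.zeros_like(f)
    if f.shape[-1] != grid.n:
        raise ValueError("field length does not match grid")
    back = (f[..., 1:-1] - f[..., :-2]) / dr
    fwd = (f[..., 2:] - f[..., 1:-1]) / dr
    cen = (f[..., 2:] - f[..., :-2]) / (2.0 * dr)
    slopes[..., 1:-1] = minmod(theta * back, cen, theta * fwd)
    # ghost f_{-1} = f_0 and f_N = f_{N-1}: minmod with a zero candidate is 0
    slopes[..., 0] = 0.0
    slopes[..., -1] = 0.0
    return slopes


def _as_face_array(G_faces, n: int) -> np.ndarray:
    g = np.asarray(G_faces, dtype=float)
    if g.ndim == 0:
        g = np.full(n + 1, float(g))
    if g.shape != (n + 1,):
        raise ValueError(f"G_faces must be scalar or length n+1={n + 1}")
    if np.any(g < 0):
        raise ValueError("growth/dissolution speed must be non-negative")
    return g


def growth_flux_divergence(f: np.ndarray, G_faces, grid: SizeGrid,
                           mode: str = "growth", theta: float = 1.5,
                           outer_bc: str = "zero_flux",
                           return_workspace: bool = False):
    """Semi-discrete rate of change of f due to growth or dissolution.

    ``mode="growth"`` (supersaturated, size increases) uses the left
    (upwind) reconstruction f_j + (dr/2)(f_r)_j at each face;
    ``mode="dissolution"`` (undersaturated) uses the right reconstruction
    f_{j+1} - (dr/2)(f_r)_{j+1} and advects toward smaller sizes.
    ``G_faces`` is the non-negative advection speed at each face (scalar or
    length n+1).

    Boundaries: the inner face carries no growth flux (nucleation is a
    separate source); the outer face is zero-flux by default
    (``outer_bc="zero_flux"``, crystals accumulate in the top class) or
    open (``outer_bc="outflow"``) for pure-advection studies.  In
    dissolution mode shrinking crystals leave through the inner face.
    """
    f = np.asarray(f, dtype=float)
    n = grid.n
    if f.shape != (n,):
        raise ValueError("field length does not match grid")
    G = _as_face_array(G_faces, n)
    if outer_bc not in ("zero_flux", "outflow"):
        raise ValueError(f"unknown outer_bc {outer_bc!r}")
    dr = grid.dr
    slopes = limited_slopes(f, grid, theta=theta)
    H = np.zeros(n + 1)
    face_vals = np.zeros(n + 1)
    if mode == "growth":
        # face i (between classes i-1 and i) sees the left state of class i-1
        left = f + 0.5 * dr * slopes
        face_vals[1:] = left
        H[1:] = G[1:] * left
        H[0] = 0.0
        face_vals[0] = 0.0
        if outer_bc == "zero_flux":
            H[-1] = 0.0
    elif mode == "dissolution":
        right = f - 0.5 * dr * slopes
        face_vals[:-1] = right
        H[:-1] = -G[:-1] * right
        H[-1] = 0.0  # nothing enters from above the largest class
        face_vals[-1] = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dfdt = -(H[1:] - H[:-1]) / dr
    if return_workspace:
        return dfdt, FluxWorkspace(slopes=slopes, face_values=face_vals, H=H,
                                   theta=theta)
    return dfdt


def nucleation_source(B: float, grid: SizeGrid) -> np.ndarray:
    """Delta nucleation source: B (#/(m^3 s)) deposited into the first class."""
    if B < 0:
        raise ValueError("nucleation rate must be non-negative")
    src = np.zeros(grid.n)
    src[0] = B / grid.dr
    return src


def mass_weights(grid: SizeGrid, rho_c: float, k_v: float) -> np.ndarray:
    """Per-class factors w_j with f_w,j = w_j * f_j (exact r^3 moment).

    f_w,j = rho_c k_v Int_{r_-}^{r_+} r^3 f dr
          = rho_c k_v f_j [(r_+)^4 - (r_-)^4] / 4

    for a class-wise constant number *density* f_j (#/m^4).  (Written with
    the class number f_j*dr in #/m^3 instead, the same integral carries an
    extra 1/dr.)
    """
    if rho_c <= 0 or k_v <= 0:
        raise ValueError("rho_c and k_v must be positive")
    faces4 = grid.r_faces**4
    return rho_c * k_v / 4.0 * (faces4[1:] - faces4[:-1])


def number_to_mass(f: np.ndarray, grid: SizeGrid, rho_c: float, k_v: float) -> np.ndarray:
    """Convert number densities to per-class crystal mass densities, kg/m^3."""
    return mass_weights(grid, rho_c, k_v) * np.asarray(f, dtype=float)


@dataclass
class CSDStats:
    """Summary statistics of a crystal size distribution (both weightings)."""

    number_mean: float      # m
    number_std: float       # m
    mass_mean: float        # m
    mass_std: float         # m
    total_number: float     # #/m^3
    total_mass: float       # kg/m^3
    empty: bool = False


def _weighted_stats(weights: np.ndarray, centers: np.ndarray) -> tuple[float, float]:
    total = weights.sum()
    if total <= 0:
        return float("nan"), float("nan")
    mean = float(np.dot(weights, centers) / total)
    var = float(np.dot(weights, (centers - mean) ** 2) / total)
    return mean, np.sqrt(max(var, 0.0))


def csd_summary(f: np.ndarray | None, grid: SizeGrid,
                f_w: np.ndarray | None = None,
                rho_c: float = 1273.0, k_v: float = np.pi / 6.0) -> CSDStats:
    """Mean size, standard deviation (number- and mass-weighted) and totals.

    Statistics are computed over class centers.  An all-zero field is
    flagged ``empty`` with NaN means.
    """
    if f is None and f_w is None:
        raise ValueError("need f and/or f_w")
    centers = grid.r_centers
    if f is not None:
        f = np.clip(np.asarray(f, dtype=float), 0.0, None)
        if f_w is None:
            f_w = number_to_mass(f, grid, rho_c, k_v)
    f_w = np.clip(np.asarray(f_w, dtype=float), 0.0, None)
    total_mass = float(f_w.sum())
    if f is not None:
        num_weights = f * grid.dr
        total_number = float(num_weights.sum())
        n_mean, n_std = _weighted_stats(num_weights, centers)
    else:
        total_number = float("nan")
        n_mean = n_std = float("nan")
    m_mean, m_std = _weighted_stats(f_w, centers)
    empty = (total_mass <= 0.0) and (not total_number > 0.0)
    return CSDStats(number_mean=n_mean, number_std=n_std,
                    mass_mean=m_mean, mass_std=m_std,
                    total_number=total_number, total_mass=total_mass,
                    empty=empty)


def advect(f0: np.ndarray, G: float, t_end: float, grid: SizeGrid,
           mode: str = "growth", theta: float = 1.5, cfl: float = 0.45,
           B: float = 0.0, outer_bc: str = "outflow") -> np.ndarray:
    """Integrate pure size-advection with the scheme, SSP-RK2 in time.

    Fixed CFL-limited time step; used for convergence/TVD studies and any
    constant-rate growth or dissolution problem.  ``B`` adds a constant
    nucleation source.
    """
    f = np.asarray(f0, dtype=float).copy()
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if G < 0:
        raise ValueError("advection speed must be non-negative")
    if t_end == 0.0 or (G == 0.0 and B == 0.0):
        return f
    if G > 0:
        dt = cfl * grid.dr / G
    else:
        dt = t_end
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    src = nucleation_source(B, grid) if B > 0 else 0.0

    def rhs(y):
        if G == 0.0:
            return np.asarray(src) + np.zeros_like(y)
        return growth_flux_divergence(y, G, grid, mode=mode, theta=theta,
                                      outer_bc=outer_bc) + src

    for _ in range(n_steps):
        f1 = f + dt * rhs(f)
        f = 0.5 * f + 0.5 * (f1 + dt * rhs(f1))
    return f
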