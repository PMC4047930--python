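"""Pressure-driven axial flow through a brush-lined pore (Brinkman equation).

The grafted layer is treated as a porous medium: the axial velocity
``v_z(r)`` obeys

    mu * (1/r) d/dr(r dv/dr) - (mu / k(r)) * v = -G,

with ``G = -dP/dz > 0`` the pressure gradient and ``k`` the local Darcy
permeability.  The pore cross-section is divided into annular shells of
thickness ``dr``; each shell carries ``k_i = a^2 / phi_i^2`` from its mean
monomer volume fraction, and polymer-free shells have infinite permeability
(the equation reduces to Stokes flow there).  Boundary conditions are
symmetry at the axis, ``v'(0) = 0``, and no slip at the wall, ``v(R) = 0``.

The primary solver is a direct tridiagonal finite-difference solve of the
piecewise boundary-value problem; a shooting solver (secant iteration on the
centerline velocity, marching the same discrete stencil outwards) is kept as
a cross-validation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import solve_banded

from .brush_meanfield import DensityProfile
from .exceptions import GeometryError, NumericalError

__all__ = [
    "FlowProblem",
    "VelocityProfile",
    "FlowRates",
    "shell_permeabilities",
    "solve_velocity",
    "solve_velocity_shooting",
    "momentum_residual",
    "flow_rate",
    "poiseuille_velocity",
    "brinkman_uniform_velocity",
]


@dataclass
class FlowProblem:
    """Geometry, driving and discretization of one flow calculation.

    ``profile`` may be ``None`` for an unmodified (polymer-free) pore.
    ``dr`` is the target shell thickness; the actual spacing is ``R/n`` with
    ``n = ceil(R/dr)`` so the grid lands exactly on the wall.
    """

    R: float
    profile: DensityProfile | None = None
    mu: float = 1.0
    G: float = 1.0
    dr: float = 1.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise GeometryError(f"pore radius must be positive, got {self.R}")
        if self.mu <= 0 or self.G <= 0:
            raise ValueError("viscosity and pressure gradient must be positive")
        if not 0 < self.dr <= self.R:
            raise ValueError(f"shell thickness must satisfy 0 < dr <= R, got {self.dr}")

    @property
    def n_shells(self) -> int:
        return int(np.ceil(self.R / self.dr))

    @property
    def grid_r(self) -> np.ndarray:
        return np.linspace(0.0, self.R, self.n_shells + 1)

    @property
    def v_z0(self) -> float:
        """Centerline velocity of the unmodified pore, ``G R^2 / (4 mu)``."""
        return self.G * self.R**2 / (4.0 * self.mu)


@dataclass
class VelocityProfile:
    grid_r: np.ndarray
    v: np.ndarray
    v_norm: np.ndarray


@dataclass(frozen=True)
class FlowRates:
    Q: float
    Q0: float

    @property
    def K(self) -> float:
        """Normalized flow rate (permeability), ``Q / Q0``."""
        return self.Q / self.Q0


def _phi_at_r(profile: DensityProfile | None, r: np.ndarray, R: float) -> np.ndarray:
    if profile is None:
        return np.zeros_like(r)
    return np.asarray(profile.phi_at(R - r))


def shell_permeabilities(
    profile: DensityProfile | None, R: float, dr: float = 1.0
) -> np.ndarray:
    """Per-shell Darcy permeability ``k_i = a^2 / phi_i^2`` (units a^2).

    ``phi_i`` is the radial mean of the volume fraction over the shell,
    evaluated exactly on the union of the shell edges and the profile's own
    grid so that step discontinuities (composite helix/coil layers) are
    apportioned by their true overlap with each shell rather than sampled at
    the edge nodes.  Polymer-free shells are returned as ``inf`` (the Stokes
    limit of the momentum equation).
    """
    n = int(np.ceil(R / dr))
    edges = np.linspace(0.0, R, n + 1)
    if profile is None:
        return np.full(n, np.inf)
    # work in h = R - r; shells reversed but means are direction-agnostic
    h_edges = R - edges[::-1]
    h_union = np.union1d(h_edges, profile.grid_h[profile.grid_h <= R])
    phi_u = np.asarray(profile.phi_at(h_union))
    seg = 0.5 * (phi_u[:-1] + phi_u[1:]) * np.diff(h_union)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum_at_edges = np.interp(h_edges, h_union, cum)
    phi_shell_h = np.diff(cum_at_edges) / np.diff(h_edges)
    phi_shell = phi_shell_h[::-1]  # back to ascending r
    with np.errstate(divide="ignore"):
        k = np.where(phi_shell > 1e-300, 1.0 / np.maximum(phi_shell, 1e-300) ** 2, np.inf)
    return k


def _node_drag(problem: FlowProblem) -> np.ndarray:
    """mu/k evaluated at the nodes (average of the adjacent shells' 1/k)."""
    k = shell_permeabilities(problem.profile, problem.R, problem.dr)
    inv_k = np.where(np.isinf(k), 0.0, 1.0 / k)
    n = problem.n_shells
    d = np.empty(n + 1)
    d[0] = inv_k[0]
    d[1:n] = 0.5 * (inv_k[:-1] + inv_k[1:])
    d[n] = inv_k[-1]
    return problem.mu * d


def solve_velocity(problem: FlowProblem) -> VelocityProfile:
    """Direct tridiagonal solve of the discrete Brinkman boundary-value problem."""
    n = problem.n_shells
    r = problem.grid_r
    dr = r[1] - r[0]
    mu, G = problem.mu, problem.G
    drag = _node_drag(problem)

    # banded storage: rows = (upper, diag, lower)
    ab = np.zeros((3, n + 1))
    rhs = np.full(n + 1, -G)
    # axis node: (1/r) d/dr(r dv/dr) -> 4 (v1 - v0)/dr^2 by symmetry
    ab[1, 0] = -4.0 * mu / dr**2 - drag[0]
    ab[0, 1] = 4.0 * mu / dr**2
    i = np.arange(1, n)
    rp = r[i] + dr / 2.0
    rm = r[i] - dr / 2.0
    ab[0, i + 1] = mu * rp / (r[i] * dr**2)
    ab[1, i] = -mu * (rp + rm) / (r[i] * dr**2) - drag[i]
    ab[2, i - 1] = mu * rm / (r[i] * dr**2)
    # wall node: Dirichlet v(R) = 0
    ab[1, n] = 1.0
    ab[2, n - 1] = 0.0
    rhs[n] = 0.0

    v = solve_banded((1, 1), ab, rhs)
    vmax = float(np.max(np.abs(v)))
    if vmax > 0 and v.min() < -1e-10 * vmax:
        raise NumericalError(
            f"negative velocity {v.min():.3e} in the Brinkman solution; "
            "the density profile input is likely invalid"
        )
    v = np.maximum(v, 0.0)
    return VelocityProfile(grid_r=r, v=v, v_norm=v / problem.v_z0)


def solve_velocity_shooting(
    problem: FlowProblem, max_iter: int = 100, tol: float = 1e-8
) -> VelocityProfile:
    """Shooting solve: guess the centerline velocity, march the discrete
    stencil outwards shell by shell (continuity of velocity and shear stress
    is built into the nodal stencil), and refine by secant iteration until
    the wall velocity vanishes relative to the centerline value."""
    n = problem.n_shells
    r = problem.grid_r
    dr = r[1] - r[0]
    mu, G = problem.mu, problem.G
    drag = _node_drag(problem)

    def march(v0: float) -> np.ndarray:
        v = np.empty(n + 1)
        v[0] = v0
        v[1] = v0 + dr**2 / (4.0 * mu) * (drag[0] * v0 - G)
        for i in range(1, n):
            rp = r[i] + dr / 2.0
            rm = r[i] - dr / 2.0
            flux = (drag[i] * v[i] - G) * r[i] * dr**2 / mu + rm * (v[i] - v[i - 1])
            v[i + 1] = v[i] + flux / rp
        return v

    v0_a = problem.v_z0
    v0_b = 0.5 * problem.v_z0
    fa = march(v0_a)[-1]
    fb = march(v0_b)[-1]
    v0 = v0_b
    for _ in range(max_iter):
        if fa == fb:
            break
        v0 = v0_b - fb * (v0_b - v0_a) / (fb - fa)
        v = march(v0)
        if abs(v[-1]) <= tol * max(abs(v0), 1e-300):
            v[-1] = 0.0
            v = np.maximum(v, 0.0)
            return VelocityProfile(grid_r=r, v=v, v_norm=v / problem.v_z0)
        v0_a, fa = v0_b, fb
        v0_b, fb = v0, v[-1]
    raise NumericalError(
        f"shooting failed to converge after {max_iter} iterations "
        f"(last bracket v0 in [{v0_a:.6e}, {v0_b:.6e}])"
    )


def momentum_residual(problem: FlowProblem, vel: VelocityProfile) -> float:
    """Maximum relative residual of the discrete momentum balance at the
    interior nodes, normalized by the driving G."""
    n = problem.n_shells
    r = vel.grid_r
    dr = r[1] - r[0]
    mu, G = problem.mu, problem.G
    drag = _node_drag(problem)
    v = vel.v
    i = np.arange(1, n)
    rp = r[i] + dr / 2.0
    rm = r[i] - dr / 2.0
    lap = mu * (rp * (v[i + 1] - v[i]) - rm * (v[i] - v[i - 1])) / (r[i] * dr**2)
    res = lap - drag[i] * v[i] + G
    res0 = 4.0 * mu * (v[1] - v[0]) / dr**2 - drag[0] * v[0] + G
    return float(max(np.max(np.abs(res)), abs(res0)) / G)


def flow_rate(vel: VelocityProfile, problem: FlowProblem) -> FlowRates:
    """Volumetric flow rate ``Q = int 2 pi r v dr`` (Simpson quadrature) and
    its Poiseuille normalization ``Q0 = pi G R^4 / (8 mu)``."""
    Q = float(simpson(2.0 * np.pi * vel.grid_r * vel.v, x=vel.grid_r))
    Q0 = np.pi * problem.G * problem.R**4 / (8.0 * problem.mu)
    return FlowRates(Q=Q, Q0=Q0)


def poiseuille_velocity(r: np.ndarray, R: float, mu: float = 1.0, G: float = 1.0) -> np.ndarray:
    """Closed-form open-pore profile ``v = G (R^2 - r^2) / (4 mu)``."""
    return G * (R**2 - np.asarray(r) ** 2) / (4.0 * mu)


def brinkman_uniform_velocity(
    r: np.ndarray, R: float, phi0: float, mu: float = 1.0, G: float = 1.0
) -> np.ndarray:
    """Closed-form Brinkman profile for a pore uniformly filled at ``phi0``:
    ``v(r) = (G k / mu) [1 - I0(r/sqrt k) / I0(R/sqrt k)]`` with
    ``k = a^2/phi0^2`` (modified Bessel functions)."""
    from scipy.special import i0e

    k = 1.0 / phi0**2
    sk = np.sqrt(k)
    r = np.asarray(r, dtype=float)
    # scaled Bessel ratio avoids overflow: I0(x)/I0(y) = i0e(x) e^{x-y} / i0e(y)
    ratio = i0e(r / sk) * np.exp((r - R) / sk) / i0e(R / sk)
    return G * k / mu * (1.0 - ratio)
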