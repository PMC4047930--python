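"""Strong-stretching mean-field theory of a brush grafted inside a cylindrical pore.

Chains of ``N`` monomers (size ``a``, taken as the length unit) are end-grafted
to the concave inner wall of a cylinder of radius ``R`` at ``sigma_g`` chains
per ``a**2``.  In the strong-stretching limit every chain follows its classical
most-probable path along the pore radius, all paths reaching the wall in the
same number of monomers.  That equal-time condition forces a harmonic
self-consistent molecular field, so the monomer volume fraction is parabolic in
the distance ``h = R - r`` from the wall,

    nu * phi(h) = lam - B * h**2,      B = 3 * pi**2 / (8 * p * N**2),

with ``nu`` the solvent-quality (excluded-volume) scalar, ``p`` the number of
monomers per effective Kuhn segment and ``lam`` a Lagrange multiplier fixed by
monomer conservation in the annular layer.  The free-end distribution
``g(h')`` follows from an Abel-type integral equation linking ``phi`` to the
local stretching ``E(h, h')``, and the equilibrium layer height ``H0``
minimizes the conformational free energy ``dF = F_vol + F_el`` per chain.

All lengths are in units of ``a`` and energies in units of ``kT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .exceptions import GeometryError, NumericalError

__all__ = [
    "V_MONOMER",
    "BrushGeometry",
    "DensityProfile",
    "EndDistribution",
    "FreeEnergyBreakdown",
    "EquilibriumBrush",
    "local_stretching",
    "stretching_prefactor",
    "solve_profile_at_height",
    "free_energy_at_height",
    "natural_height",
    "equilibrium_profile",
]

#: Volume of one monomer (sphere of diameter a, in units of a**3).
V_MONOMER = np.pi / 6.0

#: Default grid spacing for density profiles, in units of a.
GRID_SPACING = 0.25

#: Threshold below which negative end-density values are clipped silently;
#: more negative values trigger a numerical-accuracy warning.
G_NEGATIVE_TOL = 1e-8


@dataclass(frozen=True)
class BrushGeometry:
    """Pore, chain and solvent parameters of a grafted brush.

    Parameters
    ----------
    R : float
        Pore radius in units of the monomer size ``a``.
    N : float
        Monomers (residues) per grafted chain.  Physically a count, but
        fractional values are accepted: they arise for the coil block of
        composite helix/coil layers, where the mean-field description
        extends smoothly to non-integer chain lengths.
    sigma_g : float
        Grafting density in chains per ``a**2`` (the inverse of the area
        per chain ``s``).
    nu : float
        Solvent-quality scalar in ``(0, 1]``; the effective excluded volume
        is ``nu * pi * a**3 / 6``.  Good solvent is ``nu = 1``.
    p : float
        Monomers per effective Kuhn segment (``>= 1``).
    a : float
        Monomer size; fixed to 1 (it defines the length unit) but kept as a
        field so configuration files can state it explicitly.
    """

    R: float
    N: float
    sigma_g: float
    nu: float = 1.0
    p: float = 1.0
    a: float = 1.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise GeometryError(f"pore radius must be positive, got R={self.R}")
        if self.N < 1:
            raise GeometryError(f"chain length must be >= 1, got N={self.N}")
        if not self.sigma_g > 0:
            raise GeometryError(f"grafting density must be positive, got {self.sigma_g}")
        if not 0 < self.nu <= 1:
            raise GeometryError(
                "solvent-quality parameter must satisfy 0 < nu <= 1 "
                f"(second-virial treatment only), got nu={self.nu}"
            )
        if self.p < 1:
            raise GeometryError(f"monomers per Kuhn segment must be >= 1, got p={self.p}")
        if self.a != 1.0:
            raise GeometryError("a defines the length unit and must be 1")

    @property
    def polymer_content(self) -> float:
        """Grafted polymer per unit pore volume, ``P_c = 2 N sigma_g / R``."""
        return 2.0 * self.N * self.sigma_g / self.R

    @property
    def field_curvature(self) -> float:
        """Harmonic-field coefficient ``B = 3 pi^2 / (8 p N^2)`` (kT / a^2)."""
        return 3.0 * np.pi**2 / (8.0 * self.p * self.N**2)

    @property
    def monomer_target(self) -> float:
        """Conserved annular content ``R sigma_g N = int c(h) (R-h) dh``."""
        return self.R * self.sigma_g * self.N


@dataclass
class DensityProfile:
    """Monomer volume fraction on a radial grid measured from the wall."""

    grid_h: np.ndarray
    phi: np.ndarray
    H: float
    R: float
    lagrange_lambda: float
    #: Expected value of ``int c(h) (R - h) dh`` for this profile.
    monomer_content: float = 0.0

    @property
    def c(self) -> np.ndarray:
        """Monomer number density ``c = phi / (pi a^3 / 6)`` on the grid."""
        return self.phi / V_MONOMER

    def phi_at(self, h) -> np.ndarray:
        """Interpolated volume fraction; zero beyond the layer extent."""
        return np.interp(h, self.grid_h, self.phi, left=self.phi[0], right=0.0)

    def conservation_error(self) -> float:
        """Relative error of the annular monomer balance (trapezoidal)."""
        integral = np.trapezoid(self.c * (self.R - self.grid_h), self.grid_h)
        return abs(integral - self.monomer_content) / self.monomer_content


@dataclass
class EndDistribution:
    """Distribution of chain free ends over distance from the wall."""

    grid_hprime: np.ndarray
    g: np.ndarray

    def normalization(self) -> float:
        return float(np.trapezoid(self.g, self.grid_hprime))

    def second_moment(self) -> float:
        return float(np.trapezoid(self.g * self.grid_hprime**2, self.grid_hprime))


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Per-chain conformational free energy, in kT."""

    F_vol: float
    F_el: float

    @property
    def dF(self) -> float:
        return self.F_vol + self.F_el


@dataclass
class EquilibriumBrush:
    """Result of the free-energy minimization over the layer height."""

    H0: float
    profile: DensityProfile
    ends: EndDistribution
    free_energy: FreeEnergyBreakdown
    pore_spanning: bool = False


def stretching_prefactor(geom: BrushGeometry) -> float:
    """Constant in ``E(h, h') = C sqrt(h'^2 - h^2)``, fixed by the chain-length
    constraint ``int_0^{h'} dh / E = N`` for every end position ``h'``."""
    return np.pi / (2.0 * geom.N)


def local_stretching(h: float, hprime: float, geom: BrushGeometry) -> float:
    """Local stretching rate ``dh/dn`` of a chain ending at ``hprime``.

    The classical equal-time path in the harmonic field gives
    ``E(h, h') = (pi / 2N) sqrt(h'^2 - h^2)`` (a per monomer), which
    satisfies ``int_0^{h'} dh / E(h, h') = N`` exactly for every ``h'``.
    """
    if hprime > geom.R:
        raise GeometryError(f"end position hprime={hprime} exceeds pore radius R={geom.R}")
    if not 0 <= h < hprime:
        raise ValueError(f"require 0 <= h < hprime, got h={h}, hprime={hprime}")
    return stretching_prefactor(geom) * np.sqrt(hprime**2 - h**2)


# ---------------------------------------------------------------------------
# Lagrange multiplier and analytic free-energy pieces
# ---------------------------------------------------------------------------

def _moment_1(R: float, H: float) -> float:
    # int_0^H (R - h) dh
    return R * H - H**2 / 2.0


def _moment_h2(R: float, H: float) -> float:
    # int_0^H h^2 (R - h) dh
    return R * H**3 / 3.0 - H**4 / 4.0


def _moment_h4(R: float, H: float) -> float:
    # int_0^H h^4 (R - h) dh
    return R * H**5 / 5.0 - H**6 / 6.0


def _lambda_unclipped(geom: BrushGeometry, H: float) -> float:
    """Multiplier from exact annular conservation assuming phi > 0 on [0, H]."""
    B = geom.field_curvature
    target = geom.nu * V_MONOMER * geom.monomer_target
    return (target + B * _moment_h2(geom.R, H)) / _moment_1(geom.R, H)


def natural_height(geom: BrushGeometry) -> tuple[float, bool]:
    """Height at which the edge density vanishes, ``lam(H) = B H^2``.

    Returns ``(H_nat, pore_spanning)``; when even a layer spanning the whole
    pore keeps a positive edge density, ``H_nat = R`` with the flag set.
    """
    B = geom.field_curvature

    def edge(H: float) -> float:
        return _lambda_unclipped(geom, H) - B * H**2

    if edge(geom.R) > 0.0:
        return geom.R, True
    lo = geom.R * 1e-12
    return float(brentq(edge, lo, geom.R, xtol=1e-12, rtol=8.9e-16)), False


def free_energy_at_height(geom: BrushGeometry, H: float) -> FreeEnergyBreakdown:
    """Per-chain free energy of the parabolic profile confined to height ``H``.

    ``F_vol`` is the excluded-volume interaction energy; ``F_el`` uses the
    equal-time identity that a monomer at height ``h`` carries elastic energy
    ``B h^2``, so both terms reduce to closed-form polynomial integrals of the
    parabolic profile over the annular volume element.
    """
    if H > geom.R:
        raise GeometryError(f"trial height H={H} exceeds pore radius R={geom.R}")
    if H <= 0:
        raise GeometryError(f"trial height must be positive, got H={H}")
    B = geom.field_curvature
    H_nat, _ = natural_height(geom)
    H_eff = min(H, H_nat)
    lam = _lambda_unclipped(geom, H_eff)
    R = geom.R
    # int phi^2 (R-h) dh with nu*phi = lam - B h^2
    int_phi2 = (
        lam**2 * _moment_1(R, H_eff)
        - 2.0 * lam * B * _moment_h2(R, H_eff)
        + B**2 * _moment_h4(R, H_eff)
    ) / geom.nu**2
    # int phi h^2 (R-h) dh
    int_phih2 = (lam * _moment_h2(R, H_eff) - B * _moment_h4(R, H_eff)) / geom.nu
    chains = R * geom.sigma_g  # per unit length, divided by 2 pi
    F_vol = geom.nu / (2.0 * V_MONOMER) * int_phi2 / chains
    F_el = B / V_MONOMER * int_phih2 / chains
    return FreeEnergyBreakdown(F_vol=float(F_vol), F_el=float(F_el))


# ---------------------------------------------------------------------------
# Gridded profile, Abel inversion for the end distribution
# ---------------------------------------------------------------------------

def _make_grid(H: float) -> np.ndarray:
    n = max(int(np.ceil(H / GRID_SPACING)), 40)
    return np.linspace(0.0, H, n + 1)


def _lambda_on_grid(geom: BrushGeometry, grid: np.ndarray) -> float:
    """Multiplier such that the trapezoidal annular balance holds exactly on
    the grid, with the profile clipped at zero."""
    B = geom.field_curvature
    h = grid
    w = geom.R - h
    target = geom.nu * V_MONOMER * geom.monomer_target

    def residual(lam: float) -> float:
        phi_nu = np.maximum(lam - B * h**2, 0.0)
        return np.trapezoid(phi_nu * w, h) - target

    lam_hi = B * h[-1] ** 2 + target / _moment_1(geom.R, h[-1]) + 1.0
    while residual(lam_hi) < 0.0:
        lam_hi *= 2.0
        if lam_hi > 1e12:
            raise NumericalError("failed to bracket the Lagrange multiplier")
    return float(brentq(residual, 0.0, lam_hi, xtol=1e-14, rtol=8.9e-16))


def _abel_end_distribution(
    geom: BrushGeometry, grid: np.ndarray, phi: np.ndarray
) -> EndDistribution:
    """Invert ``phi(h) = v sigma_g R/(R-h) int_h^H g(h')/E(h,h') dh'`` for g.

    In the squared coordinate ``u = h'^2`` the kernel becomes the classical
    Abel kernel ``1/sqrt(u - t)``; taking ``G(u) = g(sqrt u)/(2 sqrt u)``
    piecewise-constant on each sub-interval, the kernel integrates
    analytically and the collocated system is triangular.
    """
    h = grid
    u = h**2
    m = len(h) - 1
    rhs = (
        np.pi * (geom.R - h) * phi / (2.0 * geom.N * V_MONOMER * geom.sigma_g * geom.R)
    )
    G = np.zeros(m)
    # back-substitute from the outer edge inwards
    for i in range(m - 1, -1, -1):
        t = u[i]
        w_diag = 2.0 * np.sqrt(u[i + 1] - t)
        acc = 0.0
        if i + 1 < m:
            j = np.arange(i + 1, m)
            wj = 2.0 * (np.sqrt(u[j + 1] - t) - np.sqrt(u[j] - t))
            acc = float(np.dot(wj, G[j]))
        G[i] = (rhs[i] - acc) / w_diag

    h_mid = 0.5 * (h[:-1] + h[1:])
    g = 2.0 * h_mid * G
    if g.min() < -G_NEGATIVE_TOL:
        warnings.warn(
            f"end distribution reached {g.min():.3e} < -{G_NEGATIVE_TOL:g}; "
            "Abel-inversion accuracy may be degraded",
            RuntimeWarning,
            stacklevel=3,
        )
    g = np.maximum(g, 0.0)
    norm = np.trapezoid(g, h_mid)
    if norm <= 0.0:
        raise NumericalError("end distribution vanished identically")
    return EndDistribution(grid_hprime=h_mid, g=g / norm)


def solve_profile_at_height(
    geom: BrushGeometry, H: float
) -> tuple[DensityProfile, EndDistribution, FreeEnergyBreakdown]:
    """Self-consistent parabolic profile confined to trial height ``H``.

    The multiplier is fixed so the trapezoidal annular monomer balance holds
    exactly on the returned grid; the end distribution comes from the
    triangular Abel solve; the free energy uses the closed-form quadratures.
    Trial heights beyond the natural (edge-density-vanishing) height relax to
    the natural layer: the profile support cannot exceed it for nonnegative g.
    """
    if H > geom.R:
        raise GeometryError(f"trial height H={H} exceeds pore radius R={geom.R}")
    if H <= 0:
        raise GeometryError(f"trial height must be positive, got H={H}")
    H_nat, _ = natural_height(geom)
    H_eff = min(H, H_nat)
    grid = _make_grid(H_eff)
    lam = _lambda_on_grid(geom, grid)
    B = geom.field_curvature
    phi = np.maximum(lam - B * grid**2, 0.0) / geom.nu
    if phi.max() >= 1.0:
        raise NumericalError(
            f"volume fraction reached {phi.max():.3f} >= 1; the second-virial "
            "mean field is outside its range of validity for these parameters"
        )
    profile = DensityProfile(
        grid_h=grid,
        phi=phi,
        H=float(H_eff),
        R=geom.R,
        lagrange_lambda=lam,
        monomer_content=geom.monomer_target,
    )
    ends = _abel_end_distribution(geom, grid, phi)
    fe = free_energy_at_height(geom, H_eff)
    return profile, ends, fe


def equilibrium_profile(geom: BrushGeometry) -> EquilibriumBrush:
    """Equilibrium layer height ``H0`` by free-energy minimization.

    ``dF(H)`` is minimized over the physical range ``(0, min(H_nat, R)]``
    (bounded scalar minimization, absolute tolerance 1e-4 a).  When even the
    pore-spanning layer keeps positive edge density the minimizer is pinned
    at ``H = R`` and the result is flagged ``pore_spanning``.
    """
    H_cap, spanning = natural_height(geom)
    lo = min(1e-3, H_cap * 1e-3)
    res = minimize_scalar(
        lambda H: free_energy_at_height(geom, H).dF,
        bounds=(lo, H_cap),
        method="bounded",
        options={"xatol": 1e-4},
    )
    H0 = float(res.x)
    profile, ends, fe = solve_profile_at_height(geom, H0)
    return EquilibriumBrush(
        H0=H0,
        profile=profile,
        ends=ends,
        free_energy=fe,
        pore_spanning=bool(spanning and H0 > geom.R - 1e-2),
    )
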