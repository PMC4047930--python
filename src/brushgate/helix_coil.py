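"""pH-responsive gating of a poly(L-glutamic acid) brush via the helix-coil
transition.

At low pH the glutamate side chains are protonated and the grafted chains sit
in a compact alpha-helical state hugging the pore wall; raising the pH
ionizes the side chains, destabilizes the helix and the chains expand to a
random coil that fills much of the pore.  The conformational state is
described by the Zimm-Bragg model: a per-residue propagation parameter ``s``
(helix over coil statistical weight) and a nucleation/cooperativity parameter
``sigma_zb``; the helix fraction ``theta`` follows exactly from the 2x2
transfer matrix.  The pH enters through a thermodynamic-linkage mapping of
``s`` built from the coil-state and (apparent) helix-state side-chain pKa
values.

The conformational state is mapped onto a monomer density profile with a
two-layer construction: the helical residues form a dense annulus at the wall
(packing fraction ``phi_pack``), and the remaining coil residues form a
strong-stretching brush grafted at the annulus surface.  Composing that
profile with the Brinkman flow solver yields the valve characteristic
``K(pH)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .brinkman_solver import FlowProblem, flow_rate, solve_velocity
from .brush_meanfield import (
    V_MONOMER,
    BrushGeometry,
    DensityProfile,
    EquilibriumBrush,
    equilibrium_profile,
)
from .exceptions import GeometryError

__all__ = [
    "ZimmBraggParams",
    "HelixState",
    "PLGAChain",
    "CompositeLayer",
    "PHResponse",
    "helix_fraction",
    "theta_infinity",
    "s_of_pH",
    "transition_pH",
    "plga_layer_model",
    "permeability_at_pH",
    "permeability_vs_pH",
]


@dataclass(frozen=True)
class ZimmBraggParams:
    """Zimm-Bragg and ionization parameters of the grafted polypeptide.

    ``sigma_zb``: nucleation (cooperativity) parameter, in (0, 1]; small
    values give a sharp, cooperative transition.
    ``dg_hc``: intrinsic helix-minus-coil free energy per residue at low pH
    (kT); negative favors the helix.
    ``pKa_c`` / ``pKa_h``: side-chain pKa in the coil state and the apparent
    pKa in the helix state.  ``pKa_h > pKa_c`` means ionization is harder in
    the helix, so raising the pH destabilizes it (``s`` decreases with pH).
    """

    sigma_zb: float = 1e-3
    dg_hc: float = -0.4
    pKa_c: float = 4.4
    pKa_h: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_zb <= 1:
            raise ValueError(f"cooperativity must lie in (0, 1], got {self.sigma_zb}")
        if not self.pKa_h > self.pKa_c:
            raise ValueError(
                "require pKa_h > pKa_c so ionization destabilizes the helix, "
                f"got pKa_h={self.pKa_h}, pKa_c={self.pKa_c}"
            )


@dataclass(frozen=True)
class HelixState:
    s: float
    theta: float
    N: int


@dataclass(frozen=True)
class PLGAChain:
    """Grafted polypeptide chain and the packing of its helical sublayer."""

    N: int
    phi_pack: float = 0.9

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"chain length must be >= 1, got {self.N}")
        if not 0 < self.phi_pack < 1:
            raise ValueError(f"packing fraction must lie in (0, 1), got {self.phi_pack}")


def helix_fraction(s: float, params: ZimmBraggParams, N: int) -> float:
    """Finite-chain helix fraction from the Zimm-Bragg transfer matrix.

    Statistical weight of a sequence: ``s`` per helical residue and
    ``sigma_zb`` per helical run (nucleation).  ``theta`` is the exact
    logarithmic derivative ``(1/N) dlnZ/dln s``, evaluated by propagating
    ``(Z, dZ/ds)`` through the matrix product with per-step rescaling.
    """
    if s <= 0:
        raise ValueError(f"propagation parameter must be positive, got s={s}")
    if N < 1:
        raise ValueError(f"chain length must be >= 1, got N={N}")
    sig = params.sigma_zb
    # state order (helix, coil); M[prev, curr]
    M = np.array([[s, 1.0], [sig * s, 1.0]])
    dM = np.array([[1.0, 0.0], [sig, 0.0]])
    w = np.array([sig * s, 1.0])
    dw = np.array([sig, 0.0])
    for _ in range(N - 1):
        w_new = w @ M
        dw_new = dw @ M + w @ dM
        scale = w_new.sum()
        w, dw = w_new / scale, dw_new / scale
    Z = w.sum()
    dZ = dw.sum()
    return float(s * dZ / Z / N)


def theta_infinity(s: float, sigma_zb: float) -> float:
    """Closed-form helix fraction in the long-chain limit."""
    root = np.sqrt((s - 1.0) ** 2 + 4.0 * sigma_zb * s)
    return 0.5 + (s - 1.0) / (2.0 * root)


def s_of_pH(pH, params: ZimmBraggParams):
    """Propagation parameter versus pH by thermodynamic linkage.

    ``s(pH) = exp(-dg_hc) (1 + 10^(pH-pKa_h)) / (1 + 10^(pH-pKa_c))``:
    the intrinsic low-pH value modulated by the ratio of side-chain binding
    polynomials in the two states.  Strictly decreasing in pH with plateaus
    at both extremes.
    """
    pH = np.asarray(pH, dtype=float)
    s = np.exp(-params.dg_hc) * (1.0 + 10.0 ** (pH - params.pKa_h)) / (
        1.0 + 10.0 ** (pH - params.pKa_c)
    )
    return s if s.ndim else float(s)


def transition_pH(params: ZimmBraggParams) -> float:
    """Midpoint pH* where ``s(pH*) = 1`` (bisection on the closed form)."""
    f = lambda pH: s_of_pH(pH, params) - 1.0
    lo, hi = params.pKa_c - 10.0, params.pKa_h + 10.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("s(pH) does not cross 1 for these parameters")
    return float(brentq(f, lo, hi, xtol=1e-10))


@dataclass
class CompositeLayer:
    """Two-layer (helical annulus + coil brush) density profile."""

    profile: DensityProfile
    theta: float
    t_h: float
    n_coil: float
    coil: EquilibriumBrush | None
    pore_blocked: bool = False

    @property
    def span(self) -> float:
        """Total extent of the grafted layer from the wall (a)."""
        return self.profile.H


def _helix_annulus_thickness(chain: PLGAChain, geom: BrushGeometry, theta: float) -> float:
    """Thickness of the dense helical annulus from volume balance:
    ``pi (2 R t - t^2) phi_pack = 2 pi R sigma_g theta N v_monomer``."""
    content = 2.0 * geom.R * geom.sigma_g * theta * chain.N * V_MONOMER / chain.phi_pack
    disc = geom.R**2 - content
    if disc <= 0.0:
        return geom.R
    return geom.R - np.sqrt(disc)


def plga_layer_model(
    chain: PLGAChain, geom: BrushGeometry, theta: float
) -> CompositeLayer:
    """Density profile of the grafted polypeptide layer at helix fraction theta.

    The ``theta * N`` helical residues of every chain pack into a wall-hugging
    annulus at volume fraction ``phi_pack``; the remaining
    ``N_c = (1 - theta) N`` residues form a strong-stretching coil brush
    grafted at the annulus surface ``R_eff = R - t_h`` (with the areal chain
    number conserved, ``sigma_eff = sigma_g R / R_eff``).  ``N_c`` is kept
    continuous — the mean-field coil extends smoothly to fractional chain
    lengths, and rounding would freeze the coil while the annulus still
    thins, breaking the monotone response.  A residual coil block shorter
    than one residue is dropped (sub-residue bookkeeping only).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"helix fraction must lie in [0, 1], got {theta}")
    t_h = _helix_annulus_thickness(chain, geom, theta)
    if t_h >= geom.R:
        grid = np.linspace(0.0, geom.R, 401)
        fill = min(2.0 * geom.sigma_g * theta * chain.N * V_MONOMER / geom.R, 0.99)
        profile = DensityProfile(
            grid_h=grid,
            phi=np.full_like(grid, fill),
            H=geom.R,
            R=geom.R,
            lagrange_lambda=np.nan,
            monomer_content=geom.R * geom.sigma_g * theta * chain.N,
        )
        return CompositeLayer(
            profile=profile, theta=theta, t_h=geom.R, n_coil=0, coil=None, pore_blocked=True
        )

    n_coil = (1.0 - theta) * chain.N
    coil: EquilibriumBrush | None = None
    if n_coil >= 1.0:
        R_eff = geom.R - t_h
        geom_c = replace(
            geom, R=R_eff, N=n_coil, sigma_g=geom.sigma_g * geom.R / R_eff
        )
        coil = equilibrium_profile(geom_c)

    n_helix = theta * chain.N
    content = geom.R * geom.sigma_g * (n_helix + (n_coil if coil else 0))

    if t_h <= 0.0 and coil is not None:
        profile = replace_profile_content(coil.profile, geom.R, content)
        return CompositeLayer(
            profile=profile, theta=theta, t_h=0.0, n_coil=n_coil, coil=coil
        )

    m_ann = max(int(np.ceil(t_h / 0.25)), 2)
    h_ann = np.linspace(0.0, t_h, m_ann + 1)
    phi_ann = np.full_like(h_ann, chain.phi_pack)
    if coil is not None:
        h_coil = t_h + coil.profile.grid_h
        h_coil[0] = t_h + 1e-9  # step discontinuity at the interface
        grid = np.concatenate([h_ann, h_coil])
        phi = np.concatenate([phi_ann, coil.profile.phi])
        H = t_h + coil.H0
    else:
        grid = np.concatenate([h_ann, [t_h + 1e-9]])
        phi = np.concatenate([phi_ann, [0.0]])
        H = t_h
    profile = DensityProfile(
        grid_h=grid,
        phi=phi,
        H=float(H),
        R=geom.R,
        lagrange_lambda=coil.profile.lagrange_lambda if coil else np.nan,
        monomer_content=content,
    )
    return CompositeLayer(
        profile=profile, theta=theta, t_h=float(t_h), n_coil=n_coil, coil=coil
    )


def replace_profile_content(
    profile: DensityProfile, R: float, content: float
) -> DensityProfile:
    from dataclasses import replace as _replace

    return _replace(profile, R=R, monomer_content=content)


@dataclass
class PHResponse:
    """Valve characteristic of a PLGA-grafted pore over a pH grid."""

    pH: np.ndarray
    s: np.ndarray
    theta: np.ndarray
    t_h: np.ndarray
    K: np.ndarray

    def as_curve(self):
        from .valve_model import ResponseCurve

        return ResponseCurve(alpha=self.pH, K=self.K)


def permeability_at_pH(
    chain: PLGAChain,
    geom: BrushGeometry,
    zb: ZimmBraggParams,
    pH: float,
    mu: float = 1.0,
    G: float = 1.0,
    dr: float = 1.0,
) -> tuple[float, CompositeLayer, float, float]:
    """Normalized permeability K at a single pH; returns (K, layer, s, theta)."""
    s = s_of_pH(pH, zb)
    theta = helix_fraction(s, zb, chain.N)
    layer = plga_layer_model(chain, geom, theta)
    problem = FlowProblem(R=geom.R, profile=layer.profile, mu=mu, G=G, dr=dr)
    rates = flow_rate(solve_velocity(problem), problem)
    return rates.K, layer, float(s), float(theta)


def permeability_vs_pH(
    chain: PLGAChain,
    geom: BrushGeometry,
    zb: ZimmBraggParams,
    pH_grid,
    mu: float = 1.0,
    G: float = 1.0,
    dr: float = 1.0,
) -> PHResponse:
    """Valve response K(pH): Zimm-Bragg state -> two-layer profile -> Brinkman
    flow, for each pH on an ascending grid."""
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.ndim != 1 or len(pH_grid) < 2 or np.any(np.diff(pH_grid) <= 0):
        raise ValueError("pH grid must be one-dimensional and strictly ascending")
    s_arr = np.empty_like(pH_grid)
    th_arr = np.empty_like(pH_grid)
    t_arr = np.empty_like(pH_grid)
    K_arr = np.empty_like(pH_grid)
    for j, pH in enumerate(pH_grid):
        K, layer, s, theta = permeability_at_pH(chain, geom, zb, pH, mu=mu, G=G, dr=dr)
        s_arr[j], th_arr[j], t_arr[j], K_arr[j] = s, theta, layer.t_h, K
    return PHResponse(pH=pH_grid, s=s_arr, theta=th_arr, t_h=t_arr, K=K_arr)
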