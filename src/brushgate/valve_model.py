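"""Sigmoid valve-response model, curve fitting and design-space scans.

A stimulus-responsive nanopore is characterized by its normalized
permeability as a function of a stimulus alpha (pH, temperature, solvent
quality).  The response is well described by a four-parameter logistic,

    K(alpha) = K2 + (K1 - K2) / (1 + exp(beta * (alpha - alpha0))),

with open- and closed-state plateaus ``K1`` and ``K2``, inflection point
``alpha0`` and sharpness ``beta`` (the sign of ``beta`` sets the response
direction).  The figure of merit of a pH valve is
``dK = K(pH_open) - K(pH_closed)``; design scans locate the chain length
``N*`` maximizing ``dK`` over pore radius and grafting density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .brush_meanfield import BrushGeometry
from .helix_coil import PLGAChain, ZimmBraggParams, permeability_at_pH

__all__ = [
    "SigmoidParams",
    "ResponseCurve",
    "DesignPoint",
    "ScanResult",
    "sigmoid_eval",
    "fit_sigmoid",
    "delta_K",
    "design_scan",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the logistic valve response."""

    K1: float
    K2: float
    alpha0: float
    beta: float

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("plateau permeabilities must be nonnegative")


@dataclass
class ResponseCurve:
    """Permeability sampled on an ascending stimulus grid."""

    alpha: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.alpha.ndim != 1 or self.alpha.shape != self.K.shape:
            raise ValueError("alpha and K must be matching one-dimensional arrays")
        if np.any(np.diff(self.alpha) <= 0):
            raise ValueError("stimulus grid must be strictly ascending")


@dataclass(frozen=True)
class DesignPoint:
    """One point of a design-space scan."""

    R: float
    N: int
    sigma_g: float
    P_c: float
    K_open: float
    K_closed: float
    dK: float
    closed_span: float


@dataclass
class ScanResult:
    points: list[DesignPoint]
    optima: list[dict]


def sigmoid_eval(params: SigmoidParams, alpha) -> np.ndarray:
    """Overflow-safe evaluation of the logistic response."""
    alpha = np.asarray(alpha, dtype=float)
    out = params.K2 + (params.K1 - params.K2) * expit(
        -params.beta * (alpha - params.alpha0)
    )
    return out if out.ndim else float(out)


def fit_sigmoid(curve: ResponseCurve) -> tuple[SigmoidParams, float]:
    """Nonlinear least-squares fit of the logistic response.

    Initialization: plateaus from the curve endpoints, inflection at the
    steepest sampled slope, sharpness from the central slope of a logistic
    (``dK/dalpha = -beta (K1 - K2)/4`` at the inflection).  Returns the
    fitted parameters and the RMS residual.
    """
    a, K = curve.alpha, curve.K
    if len(a) < 5:
        raise ValueError("need at least 5 points spanning both plateaus")
    K_range = K.max() - K.min()
    if K_range < 1e-12:
        raise ValueError("no transition detected: the response curve is flat")
    slopes = np.diff(K) / np.diff(a)
    j = int(np.argmax(np.abs(slopes)))
    alpha0_init = 0.5 * (a[j] + a[j + 1])
    K1_init, K2_init = float(K[0]), float(K[-1])
    denom = K1_init - K2_init
    beta_init = -4.0 * slopes[j] / denom if denom != 0 else 1.0

    def model(alpha, K1, K2, alpha0, beta):
        return K2 + (K1 - K2) * expit(-beta * (alpha - alpha0))

    popt, _ = curve_fit(
        model,
        a,
        K,
        p0=[K1_init, K2_init, alpha0_init, beta_init],
        maxfev=20000,
    )
    params = SigmoidParams(K1=max(popt[0], 0.0), K2=max(popt[1], 0.0),
                           alpha0=float(popt[2]), beta=float(popt[3]))
    rms = float(np.sqrt(np.mean((model(a, *popt) - K) ** 2)))
    return params, rms


def delta_K(curve_or_system, alpha_open: float, alpha_closed: float) -> float:
    """Permeability difference ``dK = K(alpha_open) - K(alpha_closed)``.

    Accepts a :class:`ResponseCurve` (values interpolated linearly; both
    stimuli must lie inside the sampled range) or any callable mapping a
    stimulus value to K.
    """
    if callable(curve_or_system):
        return float(curve_or_system(alpha_open) - curve_or_system(alpha_closed))
    curve = curve_or_system
    lo, hi = curve.alpha[0], curve.alpha[-1]
    for val, name in ((alpha_open, "alpha_open"), (alpha_closed, "alpha_closed")):
        if not lo <= val <= hi:
            raise ValueError(
                f"{name}={val} lies outside the evaluated range [{lo}, {hi}]"
            )
    K_open = float(np.interp(alpha_open, curve.alpha, curve.K))
    K_closed = float(np.interp(alpha_closed, curve.alpha, curve.K))
    return K_open - K_closed


def design_scan(
    R_values,
    sigma_values,
    N_grid,
    zb: ZimmBraggParams | None = None,
    pH_open: float = 3.0,
    pH_closed: float = 7.0,
    nu: float = 1.0,
    p: float = 1.0,
    phi_pack: float = 0.9,
    mu: float = 1.0,
    G: float = 1.0,
    dr: float = 1.0,
) -> ScanResult:
    """Scan ``dK = K(pH_open) - K(pH_closed)`` over pore radius, grafting
    density and chain length.

    For each (R, sigma_g) the optimum chain length ``N* = argmax dK(N)`` is
    reported, flagged ``edge=True`` when it falls on the boundary of the
    grid (widen ``N_grid`` in that case), together with the diagnostic ratio
    of the closed-state layer span to the pore radius (near 1 at the
    optimum).  The scan is fully deterministic: identical inputs give
    identical tables.
    """
    if zb is None:
        zb = ZimmBraggParams()
    N_grid = [int(n) for n in N_grid]
    if len(N_grid) < 1 or any(b <= a for a, b in zip(N_grid, N_grid[1:])):
        raise ValueError("N_grid must be ascending")
    points: list[DesignPoint] = []
    optima: list[dict] = []
    for R in R_values:
        for sigma in sigma_values:
            dKs = []
            for N in N_grid:
                chain = PLGAChain(N=N, phi_pack=phi_pack)
                geom = BrushGeometry(R=R, N=N, sigma_g=sigma, nu=nu, p=p)
                K_open, layer_o, _, _ = permeability_at_pH(
                    chain, geom, zb, pH_open, mu=mu, G=G, dr=dr
                )
                K_closed, layer_c, _, _ = permeability_at_pH(
                    chain, geom, zb, pH_closed, mu=mu, G=G, dr=dr
                )
                pt = DesignPoint(
                    R=float(R),
                    N=N,
                    sigma_g=float(sigma),
                    P_c=2.0 * N * sigma / R,
                    K_open=K_open,
                    K_closed=K_closed,
                    dK=K_open - K_closed,
                    closed_span=layer_c.span,
                )
                points.append(pt)
                dKs.append(pt.dK)
            j = int(np.argmax(dKs))
            edge = len(N_grid) == 1 or j in (0, len(N_grid) - 1)
            span = [p_.closed_span for p_ in points[-len(N_grid):]][j]
            optima.append(
                {
                    "R": float(R),
                    "sigma_g": float(sigma),
                    "N_star": N_grid[j],
                    "dK_max": float(dKs[j]),
                    "edge": bool(edge),
                    "closed_span_ratio": float(span / R),
                }
            )
    return ScanResult(points=points, optima=optima)
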