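"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from brushgate.brush_meanfield import V_MONOMER, BrushGeometry


@pytest.fixture
def pore_geom():
    """Reference grafted-pore setup: R = 100 a, N = 400, sigma_g = 0.01."""
    return BrushGeometry(R=100.0, N=400, sigma_g=0.01, nu=1.0)


def brute_force_planar_brush(geom: BrushGeometry, H_max: float, n: int = 160):
    """Independent oracle: constrained minimization of the discretized
    free-energy functional over a piecewise-constant volume-fraction profile.

    Minimizes ``sum_i [nu/(2v) phi_i^2 + (B/v) h_i^2 phi_i] (R - h_i) dh``
    subject to the annular monomer balance and ``phi >= 0`` with a generic
    SLSQP solve from a uniform start — no parabolic ansatz, no Lagrange
    bookkeeping shared with the implementation under test.

    Returns (h_centers, phi, H0) where H0 is the support edge.
    """
    B = geom.field_curvature
    d = H_max / n
    h = (np.arange(n) + 0.5) * d
    w = (geom.R - h) * d

    def functional(phi):
        return float(
            np.sum((geom.nu / (2 * V_MONOMER) * phi**2 + B / V_MONOMER * h**2 * phi) * w)
            / (geom.R * geom.sigma_g)
        )

    target = V_MONOMER * geom.monomer_target
    cons = {"type": "eq", "fun": lambda phi: np.dot(phi, w) - target}
    x0 = np.full(n, target / np.sum(w))
    res = minimize(
        functional,
        x0,
        constraints=[cons],
        bounds=[(0.0, 1.0)] * n,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    phi = res.x
    support = np.where(phi > 1e-4 * phi.max())[0]
    H0 = h[support[-1]] + 0.5 * d
    return h, phi, H0


def zimm_bragg_enumeration(s: float, sigma: float, N: int) -> float:
    """Exact helix fraction by exhaustive enumeration of all 2**N sequences,
    with weight ``s`` per helical residue and ``sigma`` per helical run."""
    Z = 0.0
    Zh = 0.0
    for bits in itertools.product((0, 1), repeat=N):
        n_h = sum(bits)
        runs = sum(1 for prev, b in zip((0,) + bits, bits) if b and not prev)
        weight = s**n_h * sigma**runs
        Z += weight
        Zh += weight * n_h
    return Zh / (Z * N)
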