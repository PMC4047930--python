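"""Unit and property tests for the concave-cylinder brush mean-field solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from brushgate.brush_meanfield import (
    BrushGeometry,
    equilibrium_profile,
    free_energy_at_height,
    local_stretching,
    natural_height,
    solve_profile_at_height,
)
from brushgate.exceptions import GeometryError

from conftest import brute_force_planar_brush


class TestLocalStretching:
    def test_chain_length_constraint_integral(self, pore_geom):
        """int_0^{h'} dh / E(h, h') must equal N for every end position."""
        for hprime in (5.0, 20.0, 60.0):
            val, _ = quad(
                lambda h: 1.0 / local_stretching(h, hprime, pore_geom),
                0.0,
                hprime,
                limit=200,
            )
            assert val == pytest.approx(pore_geom.N, rel=1e-9)

    def test_edge_value_and_vanishing_at_end(self, pore_geom):
        H = 60.0
        assert local_stretching(0.0, H, pore_geom) == pytest.approx(
            np.pi * H / (2 * pore_geom.N)
        )
        # E -> 0 as h -> hprime
        assert local_stretching(H - 1e-9, H, pore_geom) < 1e-4

    def test_doubling_N_halves_stretching(self):
        g1 = BrushGeometry(R=100.0, N=200, sigma_g=0.01)
        g2 = BrushGeometry(R=100.0, N=400, sigma_g=0.01)
        e1 = local_stretching(3.0, 50.0, g1)
        e2 = local_stretching(3.0, 50.0, g2)
        assert e1 == pytest.approx(2 * e2)

    def test_domain_and_geometry_errors(self, pore_geom):
        with pytest.raises(ValueError):
            local_stretching(5.0, 5.0, pore_geom)
        with pytest.raises(GeometryError):
            local_stretching(5.0, 101.0, pore_geom)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        frac=st.floats(0.0, 0.999),
        hprime=st.floats(1.0, 99.0),
    )
    def test_positive_below_end(self, frac, hprime):
        geom = BrushGeometry(R=100.0, N=400, sigma_g=0.01)
        assert local_stretching(frac * hprime, hprime, geom) > 0


class TestProfileAtHeight:
    def test_conservation_and_bounds(self, pore_geom):
        for H in (20.0, 40.0, 55.0):
            prof, ends, fe = solve_profile_at_height(pore_geom, H)
            assert prof.conservation_error() < 1e-6
            assert np.all(prof.phi >= 0) and prof.phi.max() < 1
            assert np.all(np.diff(prof.phi) <= 1e-14)  # nonincreasing
            assert prof.H <= pore_geom.R

    def test_end_distribution_normalized_nonnegative(self, pore_geom):
        _, ends, _ = solve_profile_at_height(pore_geom, 50.0)
        assert np.all(ends.g >= 0)
        assert ends.normalization() == pytest.approx(1.0, abs=1e-6)

    def test_vanishing_grafting_gives_empty_brush(self):
        geom = BrushGeometry(R=100.0, N=400, sigma_g=1e-8)
        eq = equilibrium_profile(geom)
        assert eq.profile.phi.max() < 1e-3
        assert eq.free_energy.dF < 1e-2

    def test_free_energy_breakdown_consistent(self, pore_geom):
        _, _, fe = solve_profile_at_height(pore_geom, 45.0)
        assert fe.F_vol >= 0 and fe.F_el >= 0
        assert fe.dF == fe.F_vol + fe.F_el

    def test_elastic_energy_matches_end_distribution_moment(self, pore_geom):
        """Closed-form F_el equals the g/E quadrature (second moment of g).

        At the natural height g vanishes smoothly at the edge and the two
        routes agree tightly; compressed layers carry an integrable 1/sqrt
        edge singularity in g that the piecewise-constant Abel scheme
        resolves more coarsely, so the tolerance is looser there.
        """
        for H, rel in ((natural_height(pore_geom)[0], 1e-3), (40.0, 0.05)):
            _, ends, fe = solve_profile_at_height(pore_geom, H)
            F_el_moment = (
                3 * np.pi**2 / (16 * pore_geom.p * pore_geom.N) * ends.second_moment()
            )
            assert F_el_moment == pytest.approx(fe.F_el, rel=rel)

    def test_geometry_errors(self, pore_geom):
        with pytest.raises(GeometryError):
            solve_profile_at_height(pore_geom, 101.0)
        with pytest.raises(GeometryError):
            solve_profile_at_height(pore_geom, -1.0)


class TestEquilibrium:
    def test_fig7_solvent_quality_ordering(self):
        """Better solvent extends the layer: H0(nu=1) > H0(nu=0.4)."""
        good = equilibrium_profile(BrushGeometry(R=100.0, N=400, sigma_g=0.01, nu=1.0))
        poor = equilibrium_profile(BrushGeometry(R=100.0, N=400, sigma_g=0.01, nu=0.4))
        assert good.H0 > poor.H0
        assert not good.pore_spanning

    @pytest.mark.parametrize(
        "param, values",
        [
            ("nu", [0.4, 0.7, 1.0]),
            ("sigma_g", [0.0033, 0.005, 0.01]),
            ("N", [200, 300, 400]),
        ],
    )
    def test_H0_monotone_in_each_parameter(self, param, values):
        base = dict(R=100.0, N=400, sigma_g=0.01, nu=1.0)
        H0s = []
        for v in values:
            kw = {**base, param: v}
            H0s.append(equilibrium_profile(BrushGeometry(**kw)).H0)
        assert all(b >= a for a, b in zip(H0s, H0s[1:]))

    def test_planar_scaling_H0_linear_in_N(self):
        g1 = BrushGeometry(R=1e4, N=50, sigma_g=0.02)
        g2 = BrushGeometry(R=1e4, N=100, sigma_g=0.02)
        ratio = equilibrium_profile(g2).H0 / equilibrium_profile(g1).H0
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_free_energy_decreases_to_natural_height(self, pore_geom):
        """Compressed layers cost free energy; dF(H) falls toward H_nat."""
        H_nat, spanning = natural_height(pore_geom)
        assert not spanning
        Hs = np.linspace(0.3 * H_nat, H_nat, 8)
        dFs = [free_energy_at_height(pore_geom, H).dF for H in Hs]
        assert all(b <= a for a, b in zip(dFs, dFs[1:]))
        eq = equilibrium_profile(pore_geom)
        assert eq.H0 == pytest.approx(H_nat, abs=1e-2)

    def test_pore_spanning_flagged(self):
        geom = BrushGeometry(R=30.0, N=400, sigma_g=0.05, nu=1.0)
        eq = equilibrium_profile(geom)
        assert eq.pore_spanning
        assert eq.H0 == pytest.approx(geom.R, abs=1e-2)

    def test_planar_limit_matches_brute_force_minimization(self):
        """SST profile and H0 agree with direct constrained minimization of
        the discretized free-energy functional (independent SLSQP path)."""
        geom = BrushGeometry(R=1e4, N=50, sigma_g=0.02, nu=1.0)
        eq = equilibrium_profile(geom)
        h, phi_oracle, H0_oracle = brute_force_planar_brush(geom, 1.6 * eq.H0)
        phi_sst = eq.profile.phi_at(h)
        l2 = np.linalg.norm(phi_oracle - phi_sst) / np.linalg.norm(phi_sst)
        assert l2 < 0.05
        assert eq.H0 == pytest.approx(H0_oracle, rel=0.02)


class TestGeometryValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(R=-1.0, N=10, sigma_g=0.01),
            dict(R=10.0, N=0, sigma_g=0.01),
            dict(R=10.0, N=10, sigma_g=-0.01),
            dict(R=10.0, N=10, sigma_g=0.01, nu=0.0),
            dict(R=10.0, N=10, sigma_g=0.01, nu=1.5),
            dict(R=10.0, N=10, sigma_g=0.01, p=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(GeometryError):
            BrushGeometry(**kw)

    def test_polymer_content(self):
        geom = BrushGeometry(R=100.0, N=400, sigma_g=0.01)
        assert geom.polymer_content == pytest.approx(2 * 400 * 0.01 / 100)
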