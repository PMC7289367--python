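"""Potential landscape, state relations and bifurcation structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipact import model
from sipact.model import (
    MultimerParameters,
    Regime,
    TAU_C,
    UnsupportedMultimerError,
    acceleration,
    bifurcation_diagram,
    coordinate_from_unfolding_degree,
    landscape_at,
    potential_energy,
    saddle_momentum,
    tau_c,
    tau_star,
    unfolding_degree,
)


class TestMultimerParameters:
    def test_q_m_closed_form(self):
        p = MultimerParameters(36)
        assert p.q_m == pytest.approx(54.0 ** (7.0 / 3.0), rel=1e-14)

    @pytest.mark.parametrize("bad", [2, 1, 0, -5, 3.5])
    def test_unsupported_sizes_rejected(self, bad):
        with pytest.raises(UnsupportedMultimerError):
            MultimerParameters(bad)

    def test_contour_length(self):
        assert MultimerParameters(10).contour_length(2.0) == 20.0


class TestPotentialAndForce:
    @pytest.mark.parametrize("q, tau, expected", [
        (0.0, 0.3, 0.0),                      # every term vanishes at the origin
        (1.0, 0.0, 0.125),                    # saddle energy at zero shear
    ])
    def test_potential_values(self, q, tau, expected):
        assert potential_energy(q, tau) == pytest.approx(expected, abs=1e-14)

    def test_potential_at_folded_state(self, params36):
        # U_0(q_m) = -(7/8) 54^{8/3} + 54^{7/3}
        expected = -0.875 * 54.0 ** (8.0 / 3.0) + 54.0 ** (7.0 / 3.0)
        assert potential_energy(params36.q_m, 0.0) == pytest.approx(expected, rel=1e-14)
        assert potential_energy(params36.q_m, 0.0) == pytest.approx(-2.5431e4, rel=1e-4)

    @pytest.mark.parametrize("q, tau, expected", [
        (1.0, 0.0, 0.0),       # equilibrium at the zero-shear saddle
        (0.0, 0.7, -1.0),      # constant restoring term survives at the origin
        (0.0, 0.0, -1.0),
    ])
    def test_force_values(self, q, tau, expected):
        assert acceleration(q, tau) == pytest.approx(expected, abs=1e-14)

    def test_force_at_folded_state(self, params36):
        # q_m^{3/7} = 3N/2 exactly
        expected = -0.2 * 54.0 + 54.0 ** (1.0 / 3.0) - 1.0
        got = acceleration(params36.q_m, 0.2)
        assert got == pytest.approx(expected, rel=1e-13)
        assert got == pytest.approx(-8.020, abs=2e-3)

    @pytest.mark.parametrize("func", [potential_energy, acceleration])
    def test_domain_errors(self, func):
        with pytest.raises(ValueError):
            func(-0.1, 0.2)
        with pytest.raises(ValueError):
            func(1.0, -0.2)

    def test_force_is_negative_potential_gradient(self, rng):
        """Central finite difference of U matches -q'' at random points."""
        q = 10 ** rng.uniform(-2, 4, size=100)
        tau = rng.uniform(0, 0.5, size=100)
        h = 1e-6 * np.maximum(q, 1.0)
        grad = (potential_energy(q + h, tau) - potential_energy(q - h, tau)) / (2 * h)
        np.testing.assert_allclose(-grad, acceleration(q, tau), rtol=1e-6, atol=1e-9)


class TestUnfoldingDegree:
    @pytest.mark.parametrize("N", [3, 10, 36, 100])
    def test_endpoints_exact(self, N):
        p = MultimerParameters(N)
        assert unfolding_degree(p.q_m, p) == 0.0
        assert unfolding_degree(0.0, p) == 1.0

    def test_derived_interior_value(self, params36):
        # (2^{-7})^{3/7} = 1/8
        assert unfolding_degree(params36.q_m * 2.0 ** -7, params36) == pytest.approx(0.875, rel=1e-14)

    def test_domain_errors(self, params36):
        with pytest.raises(ValueError):
            unfolding_degree(-1.0, params36)
        with pytest.raises(ValueError):
            unfolding_degree(params36.q_m * 1.01, params36)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(u=st.floats(0.0, 1.0), N=st.integers(3, 200))
    def test_bijection_round_trip(self, u, N):
        p = MultimerParameters(N)
        q = coordinate_from_unfolding_degree(u, p)
        assert 0.0 <= q <= p.q_m
        assert unfolding_degree(q, p) == pytest.approx(u, abs=1e-10)

    def test_strictly_decreasing(self, params36):
        q = np.linspace(0, params36.q_m, 500)
        u = unfolding_degree(q, params36)
        assert np.all(np.diff(u) < 0)


class TestLandscape:
    def test_zero_shear(self, params36):
        ls = landscape_at(0.0, params36)
        assert ls.regime is Regime.FOLDED_BISTABLE
        assert ls.q_barrier == 1.0
        assert ls.q_partial is None
        assert ls.U_barrier == pytest.approx(0.125)

    def test_partial_bistable(self, params36):
        ls = landscape_at(0.1, params36)
        assert ls.regime is Regime.PARTIAL_BISTABLE
        assert ls.q_barrier == pytest.approx(2.72, rel=2e-3)
        assert ls.q_partial == pytest.approx(491.2, rel=2e-2)
        assert 0 < ls.q_barrier < ls.q_partial < params36.q_m

    def test_monostable(self, params36):
        ls = landscape_at(0.2, params36)
        assert ls.regime is Regime.MONOSTABLE_UNFOLDED
        assert ls.q_barrier is None and ls.q_partial is None

    def test_negative_shear_rejected(self, params36):
        with pytest.raises(ValueError):
            landscape_at(-0.01, params36)

    @pytest.mark.parametrize("N", [3, 7, 36, 100])
    def test_stationary_points_are_equilibria(self, N):
        p = MultimerParameters(N)
        for tau in (0.0, 0.03, 0.08, 0.12, 0.14):
            ls = landscape_at(tau, p)
            for q in (ls.q_barrier, ls.q_partial):
                if q is not None:
                    assert abs(acceleration(q, tau)) < 1e-9

    def test_barrier_below_saddle_energy_only_at_zero_shear(self, params36):
        """The barrier location grows with shear away from q_s = 1."""
        qb = [landscape_at(t, params36).q_barrier for t in (0.0, 0.05, 0.1, 0.14)]
        assert qb[0] == 1.0
        assert np.all(np.diff(qb) > 0)


class TestBifurcationConstants:
    def test_tau_star_closed_form(self, params36):
        assert tau_star(params36) == pytest.approx((54 ** (1 / 3) - 1) / 54, rel=1e-14)
        assert tau_star(params36) == pytest.approx(0.051477, abs=1e-6)

    def test_tau_star_decreasing_in_N(self):
        vals = [tau_star(MultimerParameters(N)) for N in range(3, 101)]
        assert np.all(np.diff(vals) < 0)

    def test_tau_star_brackets_partial_branch(self, params36):
        """Just above tau_star an interior minimum exists; just below, not."""
        ts = tau_star(params36)
        eps = 1e-4
        assert landscape_at(ts * (1 + eps), params36).q_partial is not None
        assert landscape_at(ts * (1 - eps), params36).q_partial is None

    @pytest.mark.parametrize("N", [3, 36, 100])
    def test_tau_c_value_independent_of_N(self, N):
        assert tau_c(MultimerParameters(N)) == pytest.approx(4.0 / 27.0, rel=1e-15)

    @pytest.mark.parametrize("N", [3, 36, 100])
    def test_tau_c_flips_stationary_point_count(self, N):
        """Brute-force root counting flips 2 -> 0 across tau_c."""
        p = MultimerParameters(N)
        eps = 1e-6
        below = landscape_at(TAU_C - eps, p)
        above = landscape_at(TAU_C + eps, p)
        assert below.q_barrier is not None
        assert above.regime is Regime.MONOSTABLE_UNFOLDED

    def test_ordering_for_all_supported_sizes(self):
        for N in range(3, 101):
            assert tau_star(MultimerParameters(N)) < TAU_C


class TestSaddleMomentum:
    def test_reference_value(self, params36):
        expected = math.sqrt(2 * (0.125 + 0.875 * 54 ** (8 / 3) - 54 ** (7 / 3)))
        got = saddle_momentum(params36)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(225.5, abs=0.1)

    def test_increasing_in_N(self, params3, params36):
        assert saddle_momentum(params3) < saddle_momentum(params36)
        vals = [saddle_momentum(MultimerParameters(N)) for N in range(3, 60)]
        assert np.all(np.diff(vals) > 0)

    def test_css0_identity(self, params36):
        """|qdot_A| = CSS_0 * q_m^{3/7} (algebraic rearrangement)."""
        from sipact.criteria import css0
        assert saddle_momentum(params36) == pytest.approx(
            css0(params36) * params36.q_m ** (3.0 / 7.0), rel=1e-12)


class TestBifurcationDiagram:
    def test_branch_structure(self, params36):
        table = bifurcation_diagram(params36, [0.0, 0.1, 0.2])
        at0 = table[table.tau == 0.0]
        assert set(at0.branch) == {"unfolded", "folded", "barrier"}
        assert set(at0[at0.stable].u) == {0.0, 1.0}
        assert at0[at0.branch == "barrier"].u.iloc[0] == pytest.approx(
            float(unfolding_degree(1.0, params36)))

        at1 = table[table.tau == 0.1]
        assert set(at1.branch) == {"unfolded", "partial", "barrier"}
        assert at1[at1.branch == "partial"].u.iloc[0] == pytest.approx(0.738, abs=5e-3)

        at2 = table[table.tau == 0.2]
        assert list(at2.branch) == ["unfolded"]
        assert at2.u.iloc[0] == 1.0

    def test_unsorted_grid_rejected(self, params36):
        with pytest.raises(ValueError):
            bifurcation_diagram(params36, [0.1, 0.0])
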