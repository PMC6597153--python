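"""Steady states, the potential, Maxwell points and nonspatial regimes."""

import math

import numpy as np
import pytest
from scipy import integrate as sp_integrate
from scipy.optimize import brentq

from forestfronts import (
    bistable_range,
    delta_V,
    forest_steady_states,
    full_model_steady_states,
    maxwell_point,
    potential,
    savanna_subsystem_range,
)
from forestfronts.homogeneous import probe_limit_cycle
from forestfronts.model import forest_reaction, nondim_reaction


class TestForestSteadyStates:
    def test_dry_climate_only_bare_ground(self, params, no_impact):
        ss = forest_steady_states(800.0, no_impact, params)
        assert ss.roots == (0.0,)
        assert ss.stability == ("stable",)

    def test_bistable_climate_three_states(self, params, no_impact):
        ss = forest_steady_states(2000.0, no_impact, params)
        assert len(ss.roots) == 3
        assert ss.stability == ("stable", "unstable", "stable")
        assert ss.roots == tuple(sorted(ss.roots))

    def test_upper_root_satisfies_defining_equation(self, params, nd, no_impact):
        ss = forest_steady_states(2000.0, no_impact, params)
        up = ss.upper
        g = nd.alpha(2000.0, no_impact) - nd.beta(2000.0) * up - nd.f(up, 2000.0)
        assert abs(g) < 1e-10

    def test_zero_always_a_root(self, params):
        for P in (0.0, 1000.0, 2500.0, 4500.0):
            assert forest_steady_states(P, math.inf, params).roots[0] == 0.0


class TestBistableRange:
    def test_no_impact_range(self, params, no_impact):
        lo, hi = bistable_range(no_impact, params)
        assert 1000.0 < lo < 1300.0
        # the bare state destabilizes exactly where the fire threshold
        # reaches zero: P = Y_c0 / |k_c|
        assert hi == pytest.approx(0.56 / 1.43e-4, abs=1.0)

    def test_impact_shrinks_range(self, params, no_impact):
        lo0, _ = bistable_range(no_impact, params)
        lo1, _ = bistable_range(0.0, params)
        assert lo1 > lo0  # clearing pressure postpones forest persistence


class TestPotential:
    def test_zero_at_origin(self, nd):
        assert potential(0.0, 1500.0, math.inf, nd) == 0.0

    def test_gradient_is_minus_reaction(self, nd):
        h = 1e-6
        for u, P in ((0.5, 2000.0), (0.3, 1200.0), (0.8, 3000.0)):
            fd = (potential(u + h, P, math.inf, nd)
                  - potential(u - h, P, math.inf, nd)) / (2 * h)
            assert fd == pytest.approx(-float(nondim_reaction(u, P, math.inf, nd)),
                                       abs=1e-6)

    def test_arctan_term_at_threshold(self, nd):
        # at u = u_c the fire integral equals (u_c^2/2) * arctan(1)
        P = 1500.0
        uc = float(nd.u_c(P))
        fire = (potential(uc, P, math.inf, nd)
                - (nd.beta(P) * uc ** 3 / 3 - nd.alpha(P, math.inf) * uc ** 2 / 2))
        assert fire == pytest.approx(uc ** 2 / 2 * math.pi / 4, rel=1e-12)

    def test_matches_quadrature(self, nd):
        """Closed form vs numerical quadrature of u f(u) for random points."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            u = rng.uniform(0.05, 1.0)
            P = rng.uniform(300.0, 3800.0)
            quad, _ = sp_integrate.quad(
                lambda s: -float(nondim_reaction(s, P, math.inf, nd)), 0.0, u,
                limit=200)
            assert float(potential(u, P, math.inf, nd)) == pytest.approx(
                quad, abs=1e-8)


class TestDeltaVAndMaxwellPoint:
    def test_sign_above_mp_forest_invades(self, params, nd, no_impact):
        assert delta_V(2000.0, no_impact, nd) < 0

    def test_monostable_raises(self, nd, no_impact):
        with pytest.raises(ValueError, match="no front"):
            delta_V(700.0, no_impact, nd)

    def test_equals_minus_reaction_integral(self, params, nd, no_impact):
        P = 1700.0
        up = forest_steady_states(P, no_impact, params).upper
        quad, _ = sp_integrate.quad(
            lambda s: float(nondim_reaction(s, P, no_impact, nd)), 0.0, up,
            limit=200)
        assert delta_V(P, no_impact, nd) == pytest.approx(-quad, abs=1e-10)

    def test_maxwell_point_against_dimensional_quadrature(self, params, no_impact):
        """Independent oracle: the stationary-front condition in the
        dimensional model, int_0^{u+} R(F) dF = 0, located by brentq on
        direct quadrature.  The closed-form route must agree."""
        def dim_deltaV(P):
            up = forest_steady_states(P, no_impact, params).upper
            val, _ = sp_integrate.quad(
                lambda F: float(forest_reaction(F, P, no_impact, params)),
                0.0, up, limit=200)
            return -val

        oracle = brentq(dim_deltaV, 1250.0, 3000.0, xtol=1e-6)
        mp = maxwell_point(no_impact, params)
        assert mp.P_MP == pytest.approx(oracle, abs=0.01)
        assert abs(mp.deltaV_at_root) < 1e-6

    def test_impact_raises_mp(self, params, no_impact):
        assert maxwell_point(0.0, params).P_MP > maxwell_point(no_impact, params).P_MP

    def test_mp_monotone_in_z_with_no_impact_asymptote(self, params, no_impact):
        zs = [0.0, 500.0, 1000.0, 2000.0, 3000.0, 5000.0]
        vals = [maxwell_point(z, params).P_MP for z in zs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(maxwell_point(no_impact, params).P_MP,
                                         abs=2.0)


class TestFullModelEquilibria:
    def test_extinction_stable_when_too_dry(self, params):
        eqs = full_model_steady_states(0.0, math.inf, params, n_starts=10, seed=0)
        trivial = [e for e in eqs if max(e.state) < 1e-9]
        assert trivial and trivial[0].stable

    def test_equilibria_are_roots(self, hs_params):
        eqs = full_model_steady_states(1200.0, math.inf, hs_params,
                                       n_starts=20, seed=1)
        assert eqs
        assert all(e.residual < 1e-10 for e in eqs)

    def test_cycling_regime_has_no_stable_equilibrium(self, hs_params):
        eqs = full_model_steady_states(1500.0, math.inf, hs_params,
                                       n_starts=30, seed=1)
        assert not any(e.stable for e in eqs)
        assert probe_limit_cycle(1500.0, math.inf, hs_params, seed=2)


class TestSavannaSubsystem:
    def test_low_savanna_defaults_have_no_bistability(self, params):
        grid = np.arange(200.0, 3200.0, 100.0)
        assert savanna_subsystem_range(params, P_grid=grid, seed=3) == []

    def test_high_savanna_fold_window(self, hs_params):
        """The short-fire-return regime has a narrow savanna/woodland
        fold at low rainfall; outside it the subsystem is monostable."""
        grid = np.arange(400.0, 1200.0, 25.0)
        ivs = savanna_subsystem_range(hs_params, P_grid=grid, seed=3)
        assert ivs
        lo, hi = ivs[0]
        assert 450.0 <= lo <= 600.0
        assert hi <= 700.0
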