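"""Response functions, reaction terms and the nondimensional mapping."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from forestfronts import (
    ModelParameters,
    burnt_fraction,
    deforestation_rate,
    fire_threshold,
    growth_rate,
    load_parameters,
    mortality_rate,
    nondim_reaction,
    nondimensionalize,
    reaction_terms,
    save_parameters,
)
from forestfronts.model import forest_reaction, forest_reaction_du, nondim_reaction_du


class TestResponseFunctions:
    @pytest.mark.parametrize("P,species,expected", [
        (1e6, "F", 0.20),                       # saturates at r_F
        (0.0, "F", 0.0),                        # clamped below wilting point
        (1.54 / 0.003, "F", 0.0),               # exact zero crossing
        (1e6, "S", 0.09),
    ])
    def test_growth_examples(self, P, species, expected, params):
        assert growth_rate(P, species, params) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("P,species,expected", [
        (1e6, "F", 0.041),                          # dries out to baseline
        (0.0, "F", 0.041 + math.exp(-2.15)),
        (500.0, "S", 0.023 + math.exp(-0.008 * 500.0)),
        (500.0, "T", 0.023 + math.exp(-0.008 * 500.0)),  # adults share the form
    ])
    def test_mortality_examples(self, P, species, expected, params):
        assert mortality_rate(P, species, params) == pytest.approx(expected, rel=1e-12)

    def test_unknown_species_rejected(self, params):
        with pytest.raises(ValueError):
            growth_rate(100.0, "T", params)   # adult trees have no growth law
        with pytest.raises(ValueError):
            mortality_rate(100.0, "X", params)

    @pytest.mark.parametrize("P,expected", [
        (0.0, 0.56),
        (1000.0, 0.56 - 0.143),
        (3916.1, 0.0),                 # beyond Y_c0/|k_c| the threshold is gone
        (5000.0, 0.0),
    ])
    def test_fire_threshold(self, P, expected, params):
        assert fire_threshold(P, params) == pytest.approx(expected, abs=1e-12)

    def test_burnt_fraction_examples(self, params):
        # open grassland burns at the maximal rate 1/tau
        assert burnt_fraction(0.0, 0.0, 1000.0, params) == pytest.approx(1 / 2.7)
        # half-saturation exactly at the percolation threshold
        yc = float(fire_threshold(1000.0, params))
        assert burnt_fraction(yc / 2, yc / 2, 1000.0, params) == pytest.approx(1 / (2 * 2.7))
        # closed canopy at P = 0
        expected = (1 / 2.7) * 0.56 ** 4 / (0.56 ** 4 + 1.0)
        assert burnt_fraction(0.0, 1.0, 0.0, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0331, abs=5e-4)
        with pytest.raises(ValueError):
            burnt_fraction(-0.1, 0.5, 1000.0, params)

    def test_deforestation(self, params):
        assert deforestation_rate(0.0, params) == pytest.approx(0.092)
        assert deforestation_rate(1e9, params) == pytest.approx(0.0, abs=1e-300)
        half = math.log(2) / 0.0015
        assert deforestation_rate(half, params) == pytest.approx(0.046, rel=1e-12)

    def test_monotonicity_on_dense_grids(self, params):
        P = np.linspace(0.0, 6000.0, 2000)
        for sp in ("S", "F"):
            assert np.all(np.diff(growth_rate(P, sp, params)) >= 0)
        for sp in ("S", "T", "F"):
            assert np.all(np.diff(mortality_rate(P, sp, params)) <= 0)
        assert np.all(np.diff(fire_threshold(P, params)) <= 0)
        w = np.linspace(0.0, 0.99, 500)
        phi = burnt_fraction(w, np.zeros_like(w), 1000.0, params)
        assert np.all(np.diff(phi) < 0)


class TestReactionTerms:
    def test_extinction_is_equilibrium(self, params):
        assert reaction_terms(0, 0, 0, 1500.0, 100.0, params) == (0, 0, 0)

    def test_closed_forest_declines_when_dry_fire_kills(self, params):
        # wet limit, no impact: forest loss is baseline mortality plus fire
        dS, dT, dF = reaction_terms(0.0, 0.0, 1.0, 1e7, math.inf, params)
        phi = burnt_fraction(0.0, 1.0, 1e7, params)
        assert dF == pytest.approx(-0.041 - 0.46 * float(phi), rel=1e-9)
        assert dF < 0

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            reaction_terms(0.5, 0.6, 0.3, 1000.0, math.inf, params)
        with pytest.raises(ValueError):
            reaction_terms(-0.1, 0.0, 0.0, 1000.0, math.inf, params)

    def test_forest_model_reduction_matches(self, params):
        """Setting S = T = 0 must reproduce the scalar forest reaction
        through an independent code path, to machine precision."""
        F = np.linspace(0.0, 1.0, 101)
        for P in (800.0, 1438.0, 2000.0, 3500.0):
            for z in (math.inf, 500.0):
                _, _, dF = reaction_terms(np.zeros_like(F), np.zeros_like(F),
                                          F, P, z, params)
                ref = forest_reaction(F, P, z, params)
                np.testing.assert_allclose(dF, ref, atol=1e-15)


class TestNondimensionalization:
    def test_constant_values(self, params, nd):
        scale = 2.7 / 0.46
        assert nd.rho == pytest.approx(0.20 * scale)      # ~1.174
        assert nd.mu0 == pytest.approx(0.041 * scale)     # ~0.2407
        assert nd.mu == pytest.approx(math.exp(-2.15) * scale)
        assert nd.gamma == pytest.approx(0.092 * scale)
        assert nd.kappa_r == 0.003 and nd.a == 1.54 and nd.u_c0 == 0.56

    def test_invalid_scaling_rejected(self, params):
        with pytest.raises(ValueError):
            nondimensionalize(params.with_overrides(tau=-1.0))

    def test_root_equivalence_dim_vs_nondim(self, params, nd):
        """The dimensional and rescaled forest reactions must share their
        equilibria exactly (the time rescaling cannot move roots)."""
        for P in np.linspace(600.0, 3800.0, 25):
            for z in (math.inf, 1000.0):
                u = np.linspace(1e-4, 1.0, 400)
                rd = np.asarray(forest_reaction(u, P, z, params))
                rn = np.asarray(nondim_reaction(u, P, z, nd))
                sd = np.where(np.diff(np.sign(rd)))[0]
                sn = np.where(np.diff(np.sign(rn)))[0]
                assert len(sd) == len(sn)
                for i, j in zip(sd, sn):
                    root_d = brentq(lambda x: float(forest_reaction(x, P, z, params)),
                                    u[i], u[i + 1], xtol=1e-13)
                    root_n = brentq(lambda x: float(nondim_reaction(x, P, z, nd)),
                                    u[j], u[j + 1], xtol=1e-13)
                    assert root_d == pytest.approx(root_n, abs=1e-10)

    def test_nondim_reaction_basics(self, nd):
        assert nondim_reaction(0.0, 1500.0, math.inf, nd) == 0.0
        # linear growth rate at u -> 0+ is alpha - 1 because f(0) = 1
        eps = 1e-8
        alpha = float(nd.alpha(1500.0, math.inf))
        fd = float(nondim_reaction(eps, 1500.0, math.inf, nd)) / eps
        assert fd == pytest.approx(alpha - 1.0, abs=1e-6)

    @pytest.mark.parametrize("fun,dfun", [
        (forest_reaction, forest_reaction_du),
        (nondim_reaction, nondim_reaction_du),
    ])
    def test_analytic_derivatives(self, fun, dfun, params, nd):
        arg = params if fun is forest_reaction else nd
        u = np.linspace(0.02, 0.95, 40)
        for P in (900.0, 1438.0, 2600.0):
            fd = (np.asarray(fun(u + 1e-6, P, 2000.0, arg))
                  - np.asarray(fun(u - 1e-6, P, 2000.0, arg))) / 2e-6
            np.testing.assert_allclose(dfun(u, P, 2000.0, arg), fd, atol=1e-5)


class TestParameterIO:
    def test_bundled_defaults_match(self):
        from forestfronts import default_parameters
        assert default_parameters() == ModelParameters()

    def test_round_trip(self, tmp_path, hs_params):
        path = tmp_path / "p.toml"
        save_parameters(hs_params, path)
        assert load_parameters(path) == hs_params

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.toml"
        path.write_text("r_F = 0.2\nnot_a_param = 1.0\n")
        with pytest.raises(ValueError, match="unknown"):
            load_parameters(path)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(k_c=1e-4)
        with pytest.raises(ValueError):
            ModelParameters(h=1.5)
        with pytest.raises(ValueError):
            ModelParameters(tau=0.0)
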