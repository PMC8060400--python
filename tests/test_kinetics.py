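"""Talin-FAK kinetic model: Bell rate, steady-state solver vs
independent oracles, conservation, and the force/parameter sweep
regimes (linearity at α = 0.05, flattening under k3/k5 reduction)."""

import numpy as np
import pytest

from famech.coupling import linear_fit
from famech.kinetics import (
    BASE_PARAMETERS, KineticParameters, SweepResult, integrate_to_steady_state,
    k1_of_force, linearity_metric, rhs, solve_steady_state, sweep_force,
    sweep_parameter,
)

F_GRID = np.linspace(7.0, 11.0, 9)


def _random_params(rng) -> KineticParameters:
    return KineticParameters(
        k1o=rng.uniform(0.01, 1.0), k2=rng.uniform(0.5, 20.0),
        k3=rng.uniform(1e-3, 0.1), k4=rng.uniform(0.1, 5.0),
        k5=rng.uniform(0.1, 5.0), k6=rng.uniform(0.1, 5.0),
        alpha=rng.uniform(0.0, 0.2),
        T_total=rng.uniform(20.0, 300.0), F_total=rng.uniform(20.0, 300.0))


class TestBellRate:
    def test_force_and_alpha_limits(self):
        assert k1_of_force(0.1, 0.0, 25.0) == 0.1
        assert k1_of_force(0.1, 0.05, 0.0) == 0.1

    def test_published_alpha_ratio(self):
        """α = 0.05: raising f from 0 to 10 pN scales k1 by e^0.5."""
        ratio = k1_of_force(0.1, 0.05, 10.0) / k1_of_force(0.1, 0.05, 0.0)
        assert ratio == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_overflow_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            v = k1_of_force(1.0, 10.0, 100.0)
        assert np.isfinite(v)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            k1_of_force(0.1, 0.05, -1.0)


class TestRHS:
    def test_single_active_term(self):
        p = BASE_PARAMETERS.replace(alpha=0.0)
        d = rhs(np.zeros(3), p, 0.0)
        assert d[0] == pytest.approx(p.k1o * p.T_total)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_zero_at_solved_steady_state(self):
        ss = solve_steady_state(BASE_PARAMETERS, 9.0)
        d = rhs(np.array([ss.T_st, ss.FT_st, ss.pFT_st]), BASE_PARAMETERS, 9.0)
        assert np.max(np.abs(d)) < 1e-9 * BASE_PARAMETERS.T_total

    def test_two_state_talin_equilibrium(self):
        """With binding and phosphorylation off the dynamics relax to
        the analytic two-state balance T_st/T = k1/k2 (the complex
        species are then decoupled, so the relaxation oracle is the
        right solver)."""
        p = BASE_PARAMETERS.replace(k3=0.0, k4=0.0, k5=0.0, k6=0.0)
        x = integrate_to_steady_state(p, 9.0)
        k1 = k1_of_force(p.k1o, p.alpha, 9.0)
        T = p.T_total - x.sum()
        assert x[1] == pytest.approx(0.0, abs=1e-9)
        assert x[2] == pytest.approx(0.0, abs=1e-9)
        assert x[0] / T == pytest.approx(k1 / p.k2, rel=1e-6)

    def test_negative_species_rejected(self):
        with pytest.raises(ValueError):
            rhs(np.array([-1.0, 0.0, 0.0]), BASE_PARAMETERS, 9.0)


class TestSteadyState:
    def test_no_phosphorylation_source(self):
        ss = solve_steady_state(BASE_PARAMETERS.replace(k5=0.0), 9.0)
        assert ss.pFT_st == pytest.approx(0.0, abs=1e-10)

    def test_phosphorylation_balance_identity(self):
        """k5·FT_st = k6·pFT_st at any converged steady state."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = _random_params(rng)
            ss = solve_steady_state(p, rng.uniform(0, 15))
            assert p.k5 * ss.FT_st == pytest.approx(p.k6 * ss.pFT_st,
                                                    rel=1e-6, abs=1e-8)

    def test_conservation_laws(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = _random_params(rng)
            ss = solve_steady_state(p, rng.uniform(0, 15))
            assert ss.T + ss.T_st + ss.FT_st + ss.pFT_st == \
                pytest.approx(p.T_total, rel=1e-9)
            assert ss.F + ss.FT_st + ss.pFT_st == pytest.approx(p.F_total, rel=1e-9)
            assert min(ss.T, ss.T_st, ss.F, ss.FT_st, ss.pFT_st) >= 0.0

    def test_agrees_with_ode_relaxation_oracle(self):
        """Newton roots match long-time stiff integration on random
        parameter draws to 1e-6 relative in all species."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = _random_params(rng)
            f = rng.uniform(0, 15)
            ss = solve_steady_state(p, f)
            ode = integrate_to_steady_state(p, f)
            newton = np.array([ss.T_st, ss.FT_st, ss.pFT_st])
            np.testing.assert_allclose(newton, ode, rtol=1e-6,
                                       atol=1e-6 * max(p.T_total, p.F_total))

    def test_scale_invariance(self):
        """Scaling both totals and 1/k3 by c leaves fractions unchanged."""
        c = 10.0
        p1 = BASE_PARAMETERS
        p2 = p1.replace(T_total=p1.T_total * c, F_total=p1.F_total * c,
                        k3=p1.k3 / c)
        s1 = solve_steady_state(p1, 9.0)
        s2 = solve_steady_state(p2, 9.0)
        for sp in ("T", "T_st", "F", "FT_st", "pFT_st"):
            assert getattr(s2, sp) / c == pytest.approx(getattr(s1, sp), rel=1e-8)


class TestSweeps:
    def test_alpha_zero_force_independent(self):
        sw = sweep_force(BASE_PARAMETERS.replace(alpha=0.0), F_GRID)
        for sp in ("T_st", "FT_st", "pFT_st"):
            np.testing.assert_allclose(sw.table[f"{sp}_rel"], 1.0, rtol=1e-8)

    def test_base_set_linear_increase_with_force(self):
        """α = 0.05 over 7-11 pN: stretched talin, complexes and
        phosphorylated complexes all rise linearly (R² ≥ 0.99)."""
        sw = sweep_force(BASE_PARAMETERS, F_GRID)
        for sp in ("T_st", "FT_st", "pFT_st"):
            slope, r2 = linearity_metric(sw, sp)
            assert slope > 0
            assert r2 >= 0.99

    def test_t_st_nondecreasing_in_force(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            p = _random_params(rng).replace(alpha=rng.uniform(0.01, 0.1))
            sw = sweep_force(p, F_GRID)
            assert np.all(np.diff(sw.table["T_st"]) >= -1e-9)

    def test_small_alpha_insensitive_regime(self):
        """α ten-fold below 0.05 shrinks the relative pFT_st response
        to < 10% of the α = 0.05 response."""
        resp = {}
        for a in (0.05, 0.005):
            sw = sweep_force(BASE_PARAMETERS.replace(alpha=a), F_GRID)
            resp[a] = sw.table["pFT_st_rel"].iloc[-1] - 1.0
        assert resp[0.005] < 0.10 * resp[0.05]

    def test_k3_hundredfold_reduction_flattens_pft(self):
        """100-fold k3 reduction eliminates the force dependence of
        phosphorylated complexes: the absolute force response collapses
        to < 5% of the base response."""
        base = sweep_force(BASE_PARAMETERS, F_GRID).table
        low = sweep_force(BASE_PARAMETERS.replace(k3=BASE_PARAMETERS.k3 / 100), F_GRID).table
        span = lambda t: t["pFT_st"].iloc[-1] - t["pFT_st"].iloc[0]
        assert span(low) < 0.05 * span(base)

    def test_k4_increase_equals_k3_decrease(self):
        """Only the ratio k3/k4 enters the steady state: 10× up in k4
        equals 10× down in k3 for FT_st and pFT_st."""
        up = sweep_force(BASE_PARAMETERS.replace(k4=BASE_PARAMETERS.k4 * 10), F_GRID).table
        down = sweep_force(BASE_PARAMETERS.replace(k3=BASE_PARAMETERS.k3 / 10), F_GRID).table
        np.testing.assert_allclose(up["FT_st"], down["FT_st"], rtol=1e-9)
        np.testing.assert_allclose(up["pFT_st"], down["pFT_st"], rtol=1e-9)

    def test_k5_hundredfold_reduction(self):
        """k5/100 drives pFT_st to near zero while stretched talin and
        complexes keep their linear force response (R² ≥ 0.99, relative
        response within 10% of base)."""
        base = sweep_force(BASE_PARAMETERS, F_GRID)
        low = sweep_force(BASE_PARAMETERS.replace(k5=BASE_PARAMETERS.k5 / 100), F_GRID)
        assert low.table["pFT_st"].max() < 1e-3 * BASE_PARAMETERS.F_total
        for sp in ("T_st", "FT_st"):
            assert low.linearity[sp]["r2"] >= 0.99
            rb = base.table[f"{sp}_rel"].iloc[-1] - 1.0
            rl = low.table[f"{sp}_rel"].iloc[-1] - 1.0
            assert abs(rl - rb) < 0.10 * rb

    def test_sweep_parameter_family(self):
        fam = sweep_parameter(BASE_PARAMETERS, "alpha", [0.0, 0.05], F_GRID)
        assert len(fam) == 2 and all(isinstance(s, SweepResult) for s in fam)
        assert fam[0].param_value == 0.0
        np.testing.assert_allclose(fam[0].table["pFT_st_rel"], 1.0, rtol=1e-8)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sweep_parameter(BASE_PARAMETERS, "k9", [1.0], F_GRID)


class TestLinearityMetric:
    def test_flat_sweep_zero_slope(self):
        sw = sweep_force(BASE_PARAMETERS.replace(alpha=0.0), F_GRID)
        slope, _ = linearity_metric(sw, "pFT_st")
        assert slope == pytest.approx(0.0, abs=1e-8)

    def test_matches_coupling_ols_on_same_points(self):
        sw = sweep_force(BASE_PARAMETERS, F_GRID)
        slope, r2 = linearity_metric(sw, "FT_st")
        fit = linear_fit(sw.table["f"], sw.table["FT_st"])
        assert slope == pytest.approx(fit.slope, rel=1e-12)
        assert r2 == pytest.approx(fit.r2, rel=1e-12)


class TestParameterIO:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "params.yaml"
        BASE_PARAMETERS.to_yaml(path)
        assert KineticParameters.from_yaml(path) == BASE_PARAMETERS

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(k2=-1.0)
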