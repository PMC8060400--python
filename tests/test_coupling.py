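"""Coupling statistics: OLS against closed-form oracles, AICc model
comparison, group tests, heatmaps, bead regression, puller stiffness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famech.coupling import (
    aicc, akaike_weights, bead_ratio_regression, compare_linear_sigmoidal,
    dunn_posthoc, fit_force_intensity, group_compare, linear_fit,
    puller_stiffness, render_heatmap,
)
from famech.synthetic import (
    BeadGeneratorConfig, FAGeneratorConfig, generate_bead_assay,
    generate_fa_dataset,
)


def _normal_equation_ols(x, y):
    """Closed-form OLS oracle: slope/intercept from the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]


class TestLinearFit:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        x = rng.normal(0, 3, n)
        if np.ptp(x) == 0:
            return
        y = rng.normal(0, 5, n)
        fit = linear_fit(x, y)
        slope, intercept = _normal_equation_ols(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)

    def test_noiseless_printed_control_line(self):
        x = np.linspace(0, 15, 66)
        fit = linear_fit(x, 194.6 * x + 1178.0)
        assert fit.slope == pytest.approx(194.6)
        assert fit.intercept == pytest.approx(1178.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coupled

    def test_constant_intensity_flat(self):
        x = np.linspace(0, 15, 30)
        fit = linear_fit(x, np.full_like(x, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert not fit.coupled

    def test_constant_force_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit(np.full(10, 3.0), np.arange(10.0))

    def test_slope_test_matches_permutation_oracle(self):
        """On one uncoupled dataset, the t-test p agrees with a
        permutation null within Monte-Carlo error."""
        ds = generate_fa_dataset(FAGeneratorConfig(n_fas=66, coupled=False, seed=8))
        x = ds.table["force_nN"].to_numpy()
        y = ds.table["tfak_au"].to_numpy()
        obs = abs(linear_fit(x, y).slope)
        rng = np.random.default_rng(0)
        perm = np.array([abs(linear_fit(x, rng.permutation(y)).slope)
                         for _ in range(500)])
        p_perm = (1 + np.sum(perm >= obs)) / 501
        p_t = linear_fit(x, y).p_slope
        assert abs(p_perm - p_t) < 3 * np.sqrt(p_t * (1 - p_t) / 500) + 0.02

    def test_pooled_multicell_recovers_shared_slope(self):
        """Pooling FAs from several cells with one shared slope leaves
        the pooled OLS slope unbiased."""
        frames = [generate_fa_dataset(FAGeneratorConfig(n_fas=30, seed=s),
                                      cell_id=s).table for s in range(6)]
        pooled = pd.concat(frames, ignore_index=True)
        fit = fit_force_intensity(pooled, "tfak")
        assert fit.slope == pytest.approx(194.6, rel=0.15)
        assert fit.n == 180


class TestModelComparison:
    def test_weights_invariant_to_aicc_shift(self):
        a = {"m1": 10.0, "m2": 13.0, "m3": 11.5}
        w1 = akaike_weights(a)
        w2 = akaike_weights({k: v + 117.0 for k, v in a.items()})
        for k in a:
            assert w1[k] == pytest.approx(w2[k])
        assert sum(w1.values()) == pytest.approx(1.0)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(n=6, rss=1.0, k=5)

    def test_sigmoidal_truth_dominates(self):
        x = np.linspace(0, 15, 66)
        y = 1000 + 3000 / (1 + np.exp(-(x - 7) / 1.0))
        df = pd.DataFrame({"force_nN": x, "tfak_au": y, "py397_au": y})
        comp = compare_linear_sigmoidal(df, "tfak")
        assert comp.weights["sigmoidal"] > 0.99

    def test_linear_truth_prefers_linear(self):
        x = np.linspace(0, 15, 66)
        y = 100.0 + 10.0 * x
        df = pd.DataFrame({"force_nN": x, "tfak_au": y, "py397_au": y})
        comp = compare_linear_sigmoidal(df, "tfak")
        assert comp.weights["linear"] > 0.5

    def test_linear_generator_monte_carlo(self):
        """Data simulated from the linear generator at n=66, R²=0.6:
        the linear model wins by median Akaike weight."""
        weights = [compare_linear_sigmoidal(
                       generate_fa_dataset(FAGeneratorConfig(seed=s)), "tfak"
                   ).weights["linear"] for s in range(100)]
        assert np.median(weights) > 0.5
        assert 0.0 <= np.mean(np.array(weights) > 0.9) <= 1.0  # reported fraction


class TestGroupCompare:
    def test_identical_tiny_groups(self):
        with pytest.warns(UserWarning):
            gc = group_compare({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert gc.test == "mann-whitney"
        assert gc.p_value > 0.9

    def test_separated_groups(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        gc = group_compare({"a": a, "b": b})
        assert gc.p_value < 1e-4

    def test_three_group_type_i_error(self):
        """Three samples from one normal population: the chosen omnibus
        test rejects at close to the nominal 5% level."""
        rng = np.random.default_rng(42)
        rej = sum(group_compare({c: rng.normal(0, 1, 20) for c in "abc"}).p_value < 0.05
                  for _ in range(1000))
        assert abs(rej / 1000 - 0.05) < 0.02

    def test_posthoc_present_for_three_groups(self, rng):
        gc = group_compare({c: rng.normal(i, 1, 25) for i, c in enumerate("abc")})
        assert gc.posthoc is not None and len(gc.posthoc) == 3
        assert ((gc.posthoc["p_adj"] >= gc.posthoc["p_raw"] - 1e-12).all())

    def test_dunn_detects_shifted_group(self, rng):
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                  "c": rng.normal(4, 1, 40)}
        ph = dunn_posthoc(groups)
        row_ab = ph[(ph.group_a == "a") & (ph.group_b == "b")].iloc[0]
        row_ac = ph[(ph.group_a == "a") & (ph.group_b == "c")].iloc[0]
        assert row_ab["p_adj"] > 0.05 and row_ac["p_adj"] < 0.001


class TestHeatmap:
    def test_impulse_response_is_kernel(self):
        hm = render_heatmap([[25.0, 25.0]], [1.0], (0, 50, 0, 50), sigma=3.0)
        iy, ix = np.unravel_index(np.argmax(hm.grid), hm.grid.shape)
        assert (ix, iy) == (25, 25)
        assert hm.grid.sum() == pytest.approx(1.0, rel=1e-6)

    def test_linearity_two_impulses(self):
        a = render_heatmap([[10.0, 10.0]], [2.0], (0, 50, 0, 50)).grid
        b = render_heatmap([[35.0, 30.0]], [3.0], (0, 50, 0, 50)).grid
        ab = render_heatmap([[10.0, 10.0], [35.0, 30.0]], [2.0, 3.0], (0, 50, 0, 50)).grid
        np.testing.assert_allclose(ab, a + b, atol=1e-12)

    def test_mass_conserved_away_from_borders(self, rng):
        pos = rng.uniform(10, 40, (200, 2))  # ≥ 3σ from the borders
        inten = rng.uniform(0, 5, 200)
        hm = render_heatmap(pos, inten, (0, 50, 0, 50), sigma=3.0)
        assert hm.grid.sum() == pytest.approx(inten.sum(), rel=0.01)
        assert (hm.grid >= -1e-12).all()

    def test_empty_input_empty_grid(self):
        hm = render_heatmap(np.empty((0, 2)), [], (0, 50, 0, 50))
        assert hm.grid.sum() == 0.0


class TestBeadRegression:
    @pytest.mark.parametrize("slope,intercept", [(0.0345, 1.870), (0.0801, 1.721)])
    def test_noiseless_printed_lines_exact(self, slope, intercept):
        assay = generate_bead_assay(BeadGeneratorConfig(slope=slope, intercept=intercept,
                                                        noise_sd=0.0))
        fit = bead_ratio_regression(assay)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_single_force_level_rejected(self):
        assay = generate_bead_assay(BeadGeneratorConfig(force_levels=(10.0,)))
        with pytest.raises(ValueError):
            bead_ratio_regression(assay)

    def test_shuffled_ratios_uniform_p(self):
        """Permuting ratios across forces destroys the association:
        slope p-values over permutations are uniform on [0, 1]."""
        from scipy.stats import kstest
        assay = generate_bead_assay(BeadGeneratorConfig(seed=0)).table
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(400):
            shuffled = assay.assign(ratio=rng.permutation(assay["ratio"].to_numpy()))
            ps.append(bead_ratio_regression(shuffled).p_slope)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPullerStiffness:
    def test_printed_estimate(self):
        assert puller_stiffness(30.0, 1.0) == pytest.approx(0.03)
        assert puller_stiffness(30.0, 0.3) == pytest.approx(0.1)

    @given(f=st.floats(0.1, 100), d=st.floats(0.05, 5))
    @settings(max_examples=25, deadline=None)
    def test_unit_identity(self, f, d):
        assert puller_stiffness(f, d) == pytest.approx(f * 1e-3 / d, rel=1e-12)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            puller_stiffness(30.0, 0.0)
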