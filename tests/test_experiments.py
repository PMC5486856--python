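"""Statistics layer: design, transforms, regression, tests, drivers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burncontract import experiments as ex
from burncontract import observables as obs
from burncontract import parameters as par


class TestDesign:
    def test_row_count_and_level_counts(self):
        d = ex.build_factorial_design()
        assert d.n_runs == 144
        counts = [len(v) for v in d.factors.values()]
        assert counts == [2, 3, 4, 6]

    def test_levels_equally_spaced_with_endpoints(self):
        d = ex.build_factorial_design()
        assert np.allclose(d.factors["delta_M"],
                           np.linspace(1e-2, 6e-2, 6))
        dk = np.diff(d.factors["k_rho"])
        assert np.allclose(dk, 0.5e-8)
        assert d.factors["k_rho"][0] == 1.25e-8
        assert d.factors["k_rho"][-1] == 2.75e-8
        assert np.allclose(d.factors["I_w"], [0.10, 0.15, 0.20])
        assert np.allclose(d.factors["c_I"], [3.57, 3.99])

    def test_deterministic_lexicographic_order(self):
        a = ex.build_factorial_design().table
        b = ex.build_factorial_design().table
        pd.testing.assert_frame_equal(a, b)
        # last factor varies fastest
        assert np.allclose(a["delta_M"].iloc[:6], np.linspace(1e-2, 6e-2, 6))
        assert (a["c_I"].iloc[:72] == 3.57).all()


class TestTransforms:
    def test_rankit_two_values(self):
        out = ex.rankit_normalize([5.0, 7.0])
        assert out == pytest.approx([stats.norm.ppf(0.25),
                                     stats.norm.ppf(0.75)])
        assert out[1] == pytest.approx(0.6744897501960817)

    def test_rankit_sums_to_zero_and_is_monotone(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=101)
        s = ex.rankit_normalize(x)
        assert abs(s.sum()) < 1e-10
        order = np.argsort(x)
        assert np.all(np.diff(s[order]) > 0)

    def test_rankit_ties_get_average_rank(self):
        s = ex.rankit_normalize([1.0, 2.0, 2.0, 3.0])
        assert s[1] == s[2]

    def test_rankit_degenerate(self):
        with pytest.raises(ValueError):
            ex.rankit_normalize([2.0, 2.0, 2.0])

    def test_zscore(self):
        assert ex.zscore([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        z = ex.zscore(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert ex.zscore(3 * x + 2) == pytest.approx(z)   # affine invariance
        with pytest.raises(ValueError):
            ex.zscore([1.0, 1.0])


class TestRegression:
    def _synthetic(self, seed=0, n=144):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        beta = np.array([0.9, 0.3, -0.07, 0.05])
        y = X @ beta + 0.3 * rng.normal(size=n)
        return y, X

    def test_exact_single_predictor(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = X[:, 0].copy()
        reg = ex.ols_with_semipartials(y, X)
        assert reg.beta[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(reg.beta[1:], 0.0, atol=1e-10)
        assert reg.r2 == pytest.approx(1.0, abs=1e-12)

    def test_sr2_identity_delta_r2_vs_t(self):
        """sr2_i = t_i^2 (1 - R^2)/(n - p - 1): the two computation routes
        agree to 1e-10 on a synthetic 144 x 4 design."""
        y, X = self._synthetic()
        reg = ex.ols_with_semipartials(y, X)
        alt = reg.t ** 2 * (1 - reg.r2) / reg.df_resid
        assert np.allclose(reg.sr2, alt, atol=1e-10)
        assert reg.sr2.sum() <= reg.r2 + 1e-12
        assert reg.r2_adj <= reg.r2
        assert np.all(reg.ci_lower <= reg.beta)
        assert np.all(reg.beta <= reg.ci_upper)

    def test_row_order_invariance(self):
        y, X = self._synthetic(seed=2)
        reg = ex.ols_with_semipartials(y, X)
        perm = np.random.default_rng(3).permutation(len(y))
        reg_p = ex.ols_with_semipartials(y[perm], X[perm])
        assert np.allclose(reg.beta, reg_p.beta, atol=1e-12)
        assert reg.r2 == pytest.approx(reg_p.r2, abs=1e-12)
        assert np.allclose(reg.sr2, reg_p.sr2, atol=1e-12)

    def test_collinearity_reported(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        X[:, 2] = X[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            ex.ols_with_semipartials(X[:, 0], X, names=["a", "b", "a_copy"])

    def test_rankit_pipeline_recovers_single_factor_effect(self):
        """A response monotone in one continuously-varied factor: the
        Rankit scores are linear in the z-scored factor (its values sit on
        a normal-quantile grid), so that factor's sr2 captures ~all
        variance."""
        n = 144
        rng = np.random.default_rng(9)
        grid = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        dm = 3.5e-2 + 1.25e-2 * rng.permutation(grid)
        others = rng.normal(size=(n, 3))
        # orthogonalize the nuisance predictors against the real factor so
        # they cannot absorb any of its unique variance share by chance
        basis = np.column_stack([np.ones(n), dm])
        others -= basis @ np.linalg.lstsq(basis, others, rcond=None)[0]
        resp = 0.4 + np.tanh(5.0 * dm) + 1e-9 * rng.normal(size=n)
        y = ex.rankit_normalize(resp)
        X = np.column_stack([ex.zscore(dm)]
                            + [ex.zscore(others[:, k]) for k in range(3)])
        reg = ex.ols_with_semipartials(y, X,
                                       ["delta_M", "u1", "u2", "u3"])
        assert reg.sr2[0] > 0.99


class TestAndersonDarling:
    def test_near_perfect_normal_sample(self):
        x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        a2s, p = ex.anderson_darling_normality(x)
        assert a2s < 0.2
        assert p > 0.5

    def test_uniform_sample_rejected(self):
        x = np.linspace(0.0, 1.0, 100)
        a2s, p = ex.anderson_darling_normality(x)
        assert p < 0.05

    def test_critical_value_maps_to_5_percent(self):
        """Published 5% critical point for the estimated-parameters case."""
        a2s = 0.752
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_statistic_matches_library_implementation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(2.0, 3.0, size=60)
        a2s, _ = ex.anderson_darling_normality(x)
        n = len(x)
        uncorrected = a2s / (1 + 0.75 / n + 2.25 / n ** 2)
        assert uncorrected == pytest.approx(stats.anderson(x).statistic,
                                            rel=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ex.anderson_darling_normality([1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert ex.pearson_with_p(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert ex.pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = ex.pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, rel=1e-12)
        assert p == pytest.approx(0.104, abs=5e-4)

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            ex.pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _stub_engine(p, t_end, output_times):
    """Analytic stand-in engine: area shrinks with low apoptosis rate."""
    scale = float(np.clip(0.6 + 5.0 * p.delta_M + 1e6 * p.k_rho * 0.0, 0, 1))
    pts = obs.wound_boundary_points(p.c_I, 40)
    polys = np.array([pts, pts * scale])
    return obs.SimulationResult(
        times=np.asarray(output_times, dtype=float),
        boundary_polygons=polys,
        probes={"M": np.array([0.0, 100.0 / p.delta_M]),
                "rho": np.array([p.I_w * 0.1, 0.05])})


class TestMonteCarloDriver:
    def test_degenerate_spread_gives_constant_outcome(self):
        cfg = ex.MonteCarloConfig(n_draws=10, k_rho_sd=1e-30,
                                  delta_M_sd=1e-30, seed=0)
        with pytest.warns(RuntimeWarning):   # inputs cannot look normal
            mc = ex.run_probabilistic_experiment(engine=_stub_engine, cfg=cfg)
        assert mc.sd_area == pytest.approx(0.0, abs=1e-12)
        assert len(mc.draws) == 10

    def test_nonpositive_draws_are_redrawn(self):
        cfg = ex.MonteCarloConfig(n_draws=30, delta_M_mean=1e-3,
                                  delta_M_sd=5e-3, seed=0)
        mc = ex.run_probabilistic_experiment(engine=_stub_engine, cfg=cfg)
        assert mc.n_redraws > 0
        assert (mc.draws["delta_M"] > 0).all()
        assert (mc.draws["k_rho"] > 0).all()

    def test_reproducible_given_seed(self):
        cfg = ex.MonteCarloConfig(n_draws=12, seed=7)
        a = ex.run_probabilistic_experiment(engine=_stub_engine, cfg=cfg)
        b = ex.run_probabilistic_experiment(engine=_stub_engine, cfg=cfg)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_correlation_matrix_contents(self):
        cfg = ex.MonteCarloConfig(n_draws=40, seed=3)
        mc = ex.run_probabilistic_experiment(engine=_stub_engine, cfg=cfg)
        # the stub couples the area positively to delta_M by construction
        assert mc.correlations.loc["delta_M", "relative_area_day42"] > 0.9
        assert np.allclose(np.diag(mc.correlations), 1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ex.MonteCarloConfig(n_draws=1)
        with pytest.raises(ValueError):
            ex.MonteCarloConfig(k_rho_sd=0.0)


class TestFactorialDriver:
    def test_stub_run_shapes_and_reuse(self):
        table, reg = ex.run_factorial_experiment(engine=_stub_engine)
        assert len(table) == 144
        assert set(table.columns) >= {"c_I", "I_w", "k_rho", "delta_M",
                                      "relative_area_day42"}
        assert (table["relative_area_day42"] <= 1.0).all()
        assert (table["relative_area_day42"] > 0.0).all()
        idx = reg.predictors.index("delta_M")
        assert reg.beta[idx] > 0.0
        assert reg.sr2[idx] > 0.9          # the stub's only real effect
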