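import numpy as np
import pandas as pd
import pytest
import scipy.stats

import cyclomort as cm
from _oracles import dense_exposure_ols
from conftest import make_panel
from cyclomort.absorb import RankError
from cyclomort.model import (
    ControlSpec,
    DistributedLagModel,
    EdgePolicyError,
    LagSpec,
    QuadraticFit,
    cumulative_response,
    residual_diagnostics_from_arrays,
)
from cyclomort.synthetic import GroundTruth, SimulationConfig, simulate_panel


class TestDesign:
    def test_exposure_column_count(self):
        rng = np.random.default_rng(0)
        panel = make_panel(
            {s: rng.exponential(1, 48) * (rng.random(48) < 0.1) for s in ("A", "B", "C")},
            rate={s: rng.normal(80, 2, 48) for s in ("A", "B", "C")},
        )
        m = DistributedLagModel(
            panel, LagSpec(n_leads=0, n_lags=2, cumulative_horizon=2),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
        )
        d = m.build_design()
        assert d.exposure.shape[1] == 3
        assert d.exposure_names == ["wind[l=0]", "wind[l=1]", "wind[l=2]"]

    def test_all_zero_wind_flagged_and_fit_errors(self):
        panel = make_panel({"A": np.zeros(48), "B": np.zeros(48)},
                           rate={"A": np.full(48, 70.0), "B": np.full(48, 75.0)})
        m = DistributedLagModel(
            panel, LagSpec(0, 2, 2),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
        )
        d = m.build_design()
        assert d.non_identified == ["wind[l=0]", "wind[l=1]", "wind[l=2]"]
        with pytest.raises(RankError, match="non-identified"):
            m.fit()

    def test_lead_and_lag_columns_match_hand_built_index_map(self):
        # 5-month toy panel, wind values chosen so every entry is legible
        wind = {"A": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                "B": np.array([10.0, 20.0, 30.0, 40.0, 50.0])}
        panel = make_panel(wind, rate={"A": np.zeros(5), "B": np.zeros(5)})
        m = DistributedLagModel(
            panel, LagSpec(n_leads=1, n_lags=1, cumulative_horizon=1),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
        )
        d = m.build_design()
        # strict edge: months 2..4 remain; columns ordered l=-1, 0, +1
        assert list(d.est_months) == [2, 3, 4]
        expect_A = np.array([[3, 2, 1], [4, 3, 2], [5, 4, 3]], dtype=float)
        np.testing.assert_array_equal(d.exposure[:3], expect_A)
        np.testing.assert_array_equal(d.exposure[3:], expect_A * 10)

    def test_edge_policy_error_when_lags_exceed_history(self):
        # 240 requested lags on a 120-month panel: no month has history
        rng = np.random.default_rng(1)
        panel = make_panel(
            {s: rng.exponential(1, 120) * (rng.random(120) < 0.1) for s in ("A", "B")},
            rate={s: np.full(120, 70.0) for s in ("A", "B")},
        )
        with pytest.raises(EdgePolicyError, match="history"):
            DistributedLagModel(
                panel, LagSpec(n_leads=0, n_lags=240, cumulative_horizon=172)
            ).build_design()

    def test_zero_pad_keeps_all_outcome_months(self):
        wind = {"A": np.arange(1.0, 6.0), "B": np.arange(10.0, 60.0, 10.0)}
        panel = make_panel(wind, rate={"A": np.zeros(5), "B": np.zeros(5)})
        m = DistributedLagModel(
            panel, LagSpec(1, 1, 1),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
            edge="zero_pad",
        )
        d = m.build_design()
        assert list(d.est_months) == [1, 2, 3, 4, 5]
        # first month has no lag history (0), last month no lead future (0)
        assert d.exposure[0, 2] == 0.0
        assert d.exposure[4, 0] == 0.0


class TestAgainstDenseOLS:
    def test_state_fe_only_matches_dense_dummies(self):
        cfg = SimulationConfig(n_states=3, n_months=60, irf_horizon=2,
                               burn_in_months=2, trend_degree=1, seed=31)
        sim = simulate_panel(cfg)
        m = DistributedLagModel(
            sim.panel, LagSpec(n_leads=0, n_lags=2, cumulative_horizon=2),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
        )
        res = m.fit()
        beta_dense, _, _ = dense_exposure_ols(m)
        assert np.abs(res.params - beta_dense).max() < 1e-8

    def test_full_controls_match_dense_including_vcov_and_dof(self):
        cfg = SimulationConfig(n_states=4, n_months=72, irf_horizon=6,
                               burn_in_months=12, trend_degree=2, seed=11)
        sim = simulate_panel(cfg)
        m = DistributedLagModel(sim.panel, LagSpec(2, 4, 4), ControlSpec(state_trend_order=2))
        res = m.fit()
        beta_dense, vcov_dense, dof_dense = dense_exposure_ols(m)
        assert np.abs(res.params - beta_dense).max() < 1e-8
        assert res.dof_resid == dof_dense
        assert np.abs(res.vcov - vcov_dense).max() < 1e-10 * np.abs(vcov_dense).max() + 1e-16

    def test_population_weighted_fit_matches_dense_wls(self):
        cfg = SimulationConfig(n_states=3, n_months=60, irf_horizon=2,
                               burn_in_months=6, trend_degree=1, seed=13)
        sim = simulate_panel(cfg)
        m = DistributedLagModel(
            sim.panel, LagSpec(0, 2, 2),
            ControlSpec(state_trend_order=1, weights="population"),
        )
        res = m.fit()
        beta_dense, _, _ = dense_exposure_ols(m)
        assert np.abs(res.params - beta_dense).max() < 1e-8


class TestRecoveryAndInvariance:
    def test_noise_free_panel_recovers_exact_irf(self):
        cfg = SimulationConfig(n_states=6, n_months=180, irf_horizon=12,
                               noise_sd=0.0, trend_degree=2, seed=19)
        sim = simulate_panel(cfg)
        m = DistributedLagModel(sim.panel, LagSpec(0, 12, 12), ControlSpec(state_trend_order=3))
        res = m.fit()
        truth = sim.truth.irf(np.arange(13))
        assert np.abs(res.params - truth).max() < 1e-6

    def test_zero_outcome_gives_zero_coefficients_and_zero_r2(self):
        rng = np.random.default_rng(4)
        wind = {s: rng.exponential(1, 60) * (rng.random(60) < 0.15) for s in ("A", "B", "C")}
        panel = make_panel(wind, rate={s: np.zeros(60) for s in ("A", "B", "C")})
        m = DistributedLagModel(
            panel, LagSpec(0, 3, 3),
            ControlSpec(state_month_fe=False, month_of_sample_fe=False,
                        state_trend_order=0, state_seasonal_trend=False,
                        state_temperature=False, state_fe=True),
        )
        res = m.fit()
        assert np.abs(res.params).max() < 1e-12
        assert res.rsquared == 0.0

    def test_state_level_shift_absorbed_exactly(self, sim_small, lags_small, controls_small):
        res0 = DistributedLagModel(sim_small.panel, lags_small, controls_small).fit()
        df = sim_small.panel.df.copy()
        shift = 25.0  # deaths per 100,000 added to one state's rate
        mask = (df["state"] == "S03") & df["deaths"].notna()
        df.loc[mask, "deaths"] += shift * df.loc[mask, "population"] / 1e5
        res1 = DistributedLagModel(cm.StatePanel(df), lags_small, controls_small).fit()
        assert np.abs(res0.params - res1.params).max() < 1e-8

    def test_lead_falsification_rejects_at_nominal_rate(self):
        # correctly specified null-free DGP: the joint lead test's p-value
        # is uniform, so ~5% of small replicates reject at the 5% level
        pvals = []
        for seed in range(60):
            cfg = SimulationConfig(n_states=6, n_months=120, irf_horizon=6,
                                   trend_degree=1, seed=1000 + seed)
            sim = simulate_panel(cfg)
            m = DistributedLagModel(sim.panel, LagSpec(6, 6, 6),
                                    ControlSpec(state_trend_order=1))
            pvals.append(m.fit().wald_leads()[1])
        rejections = sum(p < 0.05 for p in pvals)
        assert rejections <= 9          # binomial(60, .05) 99.9% upper bound
        assert 0.3 < np.mean(pvals) < 0.7


class TestCumulativeResponse:
    def test_simple_sums(self):
        lagv = np.array([0, 1, 2])
        beta = np.array([1.0, 2.0, -1.0])
        cum = cumulative_response(lagv, beta, np.zeros((3, 3)), horizon=2)
        assert list(cum.omega) == [1.0, 3.0, 2.0]

    def test_zero_beta_gives_zero_omega(self):
        lagv = np.arange(-2, 4)
        cum = cumulative_response(lagv, np.zeros(6), np.eye(6), horizon=3)
        assert (cum.omega == 0).all()

    def test_identity_vcov_variance_sum(self):
        cum = cumulative_response(np.array([0, 1]), np.array([1.0, 1.0]), 2 * np.eye(2), 1)
        assert cum.se.loc[1] == pytest.approx(np.sqrt(4.0))
        # with identity vcov, Var(Omega_1) = 2
        cum2 = cumulative_response(np.array([0, 1]), np.array([1.0, 1.0]), np.eye(2), 1)
        assert cum2.se.loc[1] ** 2 == pytest.approx(2.0)

    def test_normalization_and_difference_identity(self, fitted_small):
        _, res = fitted_small
        cum = res.cumulative(24)
        assert cum.omega.loc[-1] == 0.0
        beta = res.beta
        for lag in [0, 1, 5, 24, -2, -3]:
            assert cum.omega.loc[lag] - cum.omega.loc[lag - 1] == pytest.approx(
                beta.loc[lag], abs=1e-12
            )

    def test_horizon_beyond_lags_errors(self, fitted_small):
        _, res = fitted_small
        with pytest.raises(ValueError, match="exceeds"):
            res.cumulative(500)

    def test_coverage_against_truth_single_fit(self, sim_small, fitted_small):
        _, res = fitted_small
        om, se = res.cumulative(24).at(24)
        truth = cm.true_cumulative(sim_small.truth, 24)
        assert abs(om - truth) < 5 * se


class TestQuadraticIRF:
    def test_reference_coefficients_peak(self):
        qf = QuadraticFit.from_coefficients(0.0237, 0.000535, -0.0000039)
        assert round(qf.peak_month, 1) == 68.6
        assert round(qf.peak_value, 3) == 0.042

    def test_exact_quadratic_recovered_to_machine_precision(self):
        lags = np.arange(0, 100)
        beta = pd.Series(0.02 + 0.001 * lags - 1e-5 * lags**2, index=lags)
        qf = QuadraticFit.from_beta(beta, (0, 99))
        assert qf.a0 == pytest.approx(0.02, abs=1e-12)
        assert qf.a1 == pytest.approx(0.001, abs=1e-12)
        assert qf.a2 == pytest.approx(-1e-5, abs=1e-14)
        assert qf.peak_month == pytest.approx(50.0, abs=1e-6)

    def test_constant_beta_has_no_peak(self):
        beta = pd.Series(0.5, index=np.arange(0, 30))
        qf = QuadraticFit.from_beta(beta, (0, 29))
        assert abs(qf.a1) < 1e-10 and abs(qf.a2) < 1e-10
        assert qf.peak_month is None and qf.peak_value is None

    def test_upward_parabola_has_no_peak(self):
        lags = np.arange(0, 30)
        qf = QuadraticFit.from_beta(pd.Series(1e-4 * lags**2, index=lags), (0, 29))
        assert qf.peak_month is None


class TestDiagnostics:
    def test_standard_normal_residual_moments(self):
        rng = np.random.default_rng(5)
        n = 100_000
        resid = rng.standard_normal(n)
        diag = residual_diagnostics_from_arrays(
            resid, row_t=np.tile(np.arange(n // 10), 10), row_state=np.repeat(np.arange(10), n // 10)
        )
        assert abs(diag.excess_kurtosis) < 0.1
        assert abs(diag.skewness) < 0.05
        assert not diag.degenerate

    def test_white_noise_autocorrelation_band(self, fitted_small):
        _, res = fitted_small
        diag = res.diagnostics()
        assert abs(diag.autocorrelations.loc[1]) < 3 / np.sqrt(res.nobs)

    def test_constant_residuals_flagged(self):
        diag = residual_diagnostics_from_arrays(
            np.full(100, 3.14), row_t=np.tile(np.arange(50), 2), row_state=np.repeat([0, 1], 50)
        )
        assert diag.degenerate
        assert diag.sd == 0.0
        assert diag.autocorrelations.isna().all()


class TestReporting:
    def test_summary_contains_key_fields(self, fitted_small):
        _, res = fitted_small
        text = res.summary()
        assert "R2" in text and "cumulative" in text and "lead falsification" in text

    def test_cluster_robust_vcov_is_psd(self, fitted_small):
        _, res = fitted_small
        V = res.vcov_clustered("state").to_numpy()
        assert np.all(np.linalg.eigvalsh((V + V.T) / 2) > -1e-10)
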