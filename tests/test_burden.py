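import numpy as np
import pandas as pd
import pytest

import cyclomort as cm
from _oracles import brute_force_burden
from cyclomort.burden import (
    BurdenError,
    counterfactual_population,
    national_trend,
    population_in_year,
    proportion_by_state,
    storm_response,
    total_burden,
    trend_decomposition,
)
from cyclomort.panel import StatePanel, calendar_month
from cyclomort.synthetic import SimulationConfig, simulate_panel


def _pop_path(states: dict[str, float], T: int = 60) -> pd.DataFrame:
    idx = pd.Index(np.arange(1, T + 1), name="t")
    return pd.DataFrame({s: np.full(T, p) for s, p in states.items()}, index=idx)


def _event(state="A", t=1, z=1.0, sid="TC1"):
    return pd.DataFrame({"storm_id": [sid], "state": [state], "t": [t], "incidence": [z]})


class TestStormResponse:
    def test_unit_conversion(self):
        # constant pop 100,000, z = 2, cumulative response 5 per 100k
        # per m/s over the horizon -> 10 excess deaths in total
        beta = np.full(5, 1.0)  # cumulative 5 at horizon 4
        pops = _pop_path({"A": 1e5})
        stream = storm_response({"state": "A", "t": 10, "incidence": 2.0}, beta, pops, horizon=4)
        assert stream.sum() == pytest.approx(10.0)

    def test_zero_incidence_zero_stream(self):
        stream = storm_response({"state": "A", "t": 10, "incidence": 0.0},
                                np.ones(5), _pop_path({"A": 1e5}), horizon=4)
        assert stream.empty

    def test_nonlinear_callable_nests_linear(self):
        beta = np.array([0.5, 0.3, 0.1])
        pops = _pop_path({"A": 2e5})
        ev = {"state": "A", "t": 5, "incidence": 3.0}
        lin = storm_response(ev, beta, pops, horizon=2)
        nonlin = storm_response(ev, lambda z: beta * z, pops, horizon=2)
        pd.testing.assert_series_equal(lin, nonlin)

    def test_short_population_path_errors_without_truncation(self):
        pops = _pop_path({"A": 1e5}, T=10)
        ev = {"state": "A", "t": 8, "incidence": 1.0}
        with pytest.raises(BurdenError, match="truncate"):
            storm_response(ev, np.ones(6), pops, horizon=5, truncate=False)
        stream = storm_response(ev, np.ones(6), pops, horizon=5, truncate=True)
        assert list(stream.index) == [8, 9, 10]


class TestTotalBurden:
    def test_two_storms_superpose_exactly(self):
        beta = np.array([1.0, 0.5, 0.25])
        pops = _pop_path({"A": 1e5, "B": 3e5})
        e1 = _event("A", 5, 2.0, "TC1")
        e2 = _event("B", 20, 1.5, "TC2")
        both = total_burden(pd.concat([e1, e2], ignore_index=True), beta, pops, 2)
        only1 = total_burden(e1, beta, pops, 2)
        only2 = total_burden(e2, beta, pops, 2)
        pd.testing.assert_series_equal(both.national, only1.national + only2.national)
        assert both.total == pytest.approx(only1.total + only2.total)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(8)
        states = ["A", "B", "C"]
        pops = pd.DataFrame(
            rng.uniform(5e4, 5e5, (80, 3)),
            index=pd.Index(np.arange(1, 81), name="t"), columns=states,
        )
        events = pd.DataFrame(
            {
                "storm_id": [f"TC{i}" for i in range(12)],
                "state": rng.choice(states, 12),
                "t": rng.integers(1, 70, 12),
                "incidence": rng.lognormal(1, 0.8, 12),
            }
        )
        beta = rng.normal(0.05, 0.02, 13)
        res = total_burden(events, beta, pops, horizon=12)
        oracle_total, oracle_monthly = brute_force_burden(events, beta, pops, 12)
        assert res.total == pytest.approx(oracle_total, rel=1e-12)
        for t, v in oracle_monthly.items():
            assert res.national.loc[t] == pytest.approx(v, rel=1e-12)

    def test_empty_catalog_zero_burden(self):
        pops = _pop_path({"A": 1e5})
        empty = pd.DataFrame(columns=["storm_id", "state", "t", "incidence"])
        res = total_burden(empty, np.ones(3), pops, 2)
        assert res.total == 0.0
        assert (res.national == 0).all()
        assert res.per_storm_average == 0.0

    def test_per_storm_average_uses_distinct_storms(self):
        # one storm hitting two states counts once in the denominator
        beta = np.array([1.0])
        pops = _pop_path({"A": 1e5, "B": 1e5})
        events = pd.DataFrame(
            {"storm_id": ["TC1", "TC1"], "state": ["A", "B"], "t": [5, 5],
             "incidence": [2.0, 3.0]}
        )
        res = total_burden(events, beta, pops, 0)
        assert res.n_storms == 1
        assert res.per_storm_average == pytest.approx(res.total)

    def test_linearity_in_incidence(self):
        beta = np.array([0.3, 0.2, 0.1])
        pops = _pop_path({"A": 2e5})
        ev = _event("A", 10, 1.7)
        ev_scaled = ev.assign(incidence=ev["incidence"] * 3.5)
        r1 = total_burden(ev, beta, pops, 2)
        r2 = total_burden(ev_scaled, beta, pops, 2)
        assert r2.total == pytest.approx(3.5 * r1.total, rel=1e-12)

    def test_missing_group_response_raises(self):
        pops = _pop_path({"A": 1e5})
        with pytest.raises(BurdenError, match="no response assignment"):
            total_burden(_event("A"), {"high": np.ones(3)}, pops, 2,
                         state_groups={"A": "low"})


class TestProportions:
    def test_simple_ratio(self, sim_small):
        panel = sim_small.panel
        pops = panel.pivot("population").loc[1:]
        # a single synthetic storm with known burden
        beta = np.array([10.0])
        ev = _event(panel.states[0], 5, 1.0)
        res = total_burden(ev, beta, pops, 0)
        prop = proportion_by_state(res, panel)
        deaths0 = panel.df[panel.df["state"] == panel.states[0]]["deaths"].sum()
        assert prop[panel.states[0]] == pytest.approx(res.total / deaths0)
        assert (prop.drop(panel.states[0]) == 0).all()

    def test_injected_attributable_fraction_recovered(self):
        # generate with a known IRF, fit, attribute: the recovered
        # proportion matches the truth-implied share
        cfg = SimulationConfig(n_states=8, n_months=240, irf_horizon=12,
                               trend_degree=2, seed=23)
        sim = simulate_panel(cfg)
        model = cm.DistributedLagModel(
            sim.panel, cm.LagSpec(0, 12, 12), cm.ControlSpec(state_trend_order=2)
        )
        res = model.fit()
        pops = sim.panel.pivot("population").loc[1:]
        obs_ev = sim.events[sim.events["t"] >= 1]
        est = total_burden(obs_ev, res.beta.loc[0:12], pops, 12)
        true = total_burden(obs_ev, sim.truth.irf(np.arange(13)), pops, 12)
        p_est = proportion_by_state(est, sim.panel).sum()
        p_true = proportion_by_state(true, sim.panel).sum()
        # the proportion inherits the sampling noise of Omega_hat, so the
        # band scales with its standard error relative to the true value
        om_true = cm.true_cumulative(sim.truth, 12)
        _, se = res.cumulative(12).at(12)
        assert abs(p_est - p_true) / p_true < 4 * se / om_true


class TestPopulationScenarios:
    @staticmethod
    def _panel_with_pops(popA, popB, T=24):
        t = np.arange(1, T + 1)
        rows = []
        for s, pops in (("A", popA), ("B", popB)):
            rows.append(pd.DataFrame({
                "state": s, "t": t, "month": calendar_month(t), "wind": 0.0,
                "temperature": 15.0, "deaths": 10.0, "population": pops,
            }))
        return StatePanel(pd.concat(rows, ignore_index=True))

    def test_deflation_worked_example(self):
        # 1950 totals {A:60, B:40}; 2015 {A:90, B:110} -> Delta = 1,
        # deflated {A:45, B:55}, national total back to 100
        popA = np.concatenate([np.full(12, 60.0), np.full(12, 90.0)])
        popB = np.concatenate([np.full(12, 40.0), np.full(12, 110.0)])
        panel = self._panel_with_pops(popA, popB)
        sc = counterfactual_population(panel, "deflated", base_year=1, target_year=2)
        assert sc.delta == pytest.approx(1.0)
        assert sc.path["A"].iloc[0] == pytest.approx(45.0)
        assert sc.path["B"].iloc[0] == pytest.approx(55.0)
        assert sc.path.iloc[0].sum() == pytest.approx(100.0)

    def test_same_base_and_target_is_identity_scale(self):
        popA = np.linspace(50, 80, 24)
        popB = np.linspace(40, 45, 24)
        panel = self._panel_with_pops(popA, popB)
        sc = counterfactual_population(panel, "deflated", base_year=2, target_year=2)
        assert sc.delta == pytest.approx(0.0)
        assert sc.path["A"].iloc[0] == pytest.approx(population_in_year(panel, 2)["A"])

    def test_fixed_year_path_is_time_constant(self):
        panel = self._panel_with_pops(np.linspace(50, 80, 24), np.linspace(40, 45, 24))
        sc = counterfactual_population(panel, "fixed_year", target_year=1)
        assert (sc.path.nunique(axis=0) == 1).all()

    def test_deflated_total_conserved_over_random_panels(self):
        # conservation: deflated national total equals the base-year total
        for seed in range(100):
            rng = np.random.default_rng(seed)
            popA = rng.uniform(1e4, 1e6) * np.exp(np.linspace(0, rng.uniform(0, 1), 24))
            popB = rng.uniform(1e4, 1e6) * np.exp(np.linspace(0, rng.uniform(0, 1), 24))
            panel = self._panel_with_pops(popA, popB)
            sc = counterfactual_population(panel, "deflated", base_year=1, target_year=2)
            base_total = population_in_year(panel, 1).sum()
            assert sc.path.iloc[0].sum() == pytest.approx(base_total, rel=1e-12)

    def test_missing_year_errors(self):
        panel = self._panel_with_pops(np.full(24, 60.0), np.full(24, 40.0))
        with pytest.raises(BurdenError, match="not fully present"):
            counterfactual_population(panel, "fixed_year", target_year=5)


class TestTrendDecomposition:
    def test_stationary_climate_fixed_population_flat_trend(self):
        rng = np.random.default_rng(12)
        pops = _pop_path({"A": 1e5, "B": 1e5}, T=240)
        events = pd.DataFrame({
            "storm_id": [f"TC{i}" for i in range(80)],
            "state": rng.choice(["A", "B"], 80),
            "t": rng.integers(1, 230, 80),
            "incidence": rng.lognormal(1, 0.5, 80),
        })
        beta = np.full(13, 0.05)
        res = total_burden(events, beta, pops, 12)
        scale = res.national.mean()
        assert abs(res.trend) < 0.02 * scale

    def test_growing_population_raises_trend_vs_fixed(self):
        # population doubles mid-sample; storms stationary
        T = 240
        t = np.arange(1, T + 1)
        pop = np.where(t <= T // 2, 1e5, 2e5).astype(float)
        rows = []
        for s in ("A", "B"):
            rows.append(pd.DataFrame({
                "state": s, "t": t, "month": calendar_month(t), "wind": 0.0,
                "temperature": 15.0, "deaths": 50.0, "population": pop,
            }))
        panel = StatePanel(pd.concat(rows, ignore_index=True))
        rng = np.random.default_rng(3)
        events = pd.DataFrame({
            "storm_id": [f"TC{i}" for i in range(100)],
            "state": rng.choice(["A", "B"], 100),
            "t": rng.integers(1, T - 12, 100),
            "incidence": rng.lognormal(1, 0.5, 100),
        })
        beta = np.full(13, 0.05)
        scenarios = {
            "actual": counterfactual_population(panel, "actual"),
            "fixed": counterfactual_population(panel, "fixed_year", target_year=1),
        }
        dec = trend_decomposition(events, beta, scenarios, 12)
        assert dec.loc["actual", "trend"] > dec.loc["fixed", "trend"]

    def test_spatial_redistribution_isolated(self):
        # storms hit only state A; population share shifts toward A by
        # the end year.  Deflated (end shares, base total) vs fixed-base
        # isolates the spatial effect: more exposed population -> more
        # burden at equal national total.
        T = 48
        t = np.arange(1, T + 1)
        popA = np.linspace(5e4, 1.5e5, T)
        popB = np.linspace(1.5e5, 5e4, T)
        rows = []
        for s, p in (("A", popA), ("B", popB)):
            rows.append(pd.DataFrame({
                "state": s, "t": t, "month": calendar_month(t), "wind": 0.0,
                "temperature": 15.0, "deaths": 50.0, "population": p,
            }))
        panel = StatePanel(pd.concat(rows, ignore_index=True))
        rng = np.random.default_rng(5)
        events = pd.DataFrame({
            "storm_id": [f"TC{i}" for i in range(30)],
            "state": "A",
            "t": rng.integers(1, T - 6, 30),
            "incidence": rng.lognormal(1, 0.5, 30),
        })
        beta = np.full(7, 0.1)
        fixed_base = counterfactual_population(panel, "fixed_year", target_year=1)
        deflated = counterfactual_population(panel, "deflated", base_year=1, target_year=4)
        b_fixed = total_burden(events, beta, fixed_base.path, 6)
        b_defl = total_burden(events, beta, deflated.path, 6)
        # national totals match by construction, spatial shares differ
        assert deflated.path.iloc[0].sum() == pytest.approx(fixed_base.path.iloc[0].sum())
        assert b_defl.total > b_fixed.total

    def test_short_scenario_rejected(self):
        pops = _pop_path({"A": 1e5}, T=12)
        with pytest.raises(BurdenError, match="24 months"):
            national_trend(pd.Series(np.zeros(12), index=pops.index))
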