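from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cyclomort as cm
from cyclomort.panel import StatePanel, calendar_month


@pytest.fixture(scope="session")
def sim_small() -> cm.SimulationResult:
    """Workhorse synthetic study: 10 states x 20 years, 24-month IRF."""
    cfg = cm.SimulationConfig(
        n_states=10, n_months=240, irf_horizon=24, trend_degree=3, seed=42
    )
    return cm.simulate_panel(cfg)


@pytest.fixture(scope="session")
def lags_small() -> cm.LagSpec:
    return cm.LagSpec(n_leads=6, n_lags=24, cumulative_horizon=24)


@pytest.fixture(scope="session")
def controls_small() -> cm.ControlSpec:
    return cm.ControlSpec(state_trend_order=3)


@pytest.fixture(scope="session")
def fitted_small(sim_small, lags_small, controls_small):
    model = cm.DistributedLagModel(sim_small.panel, lags_small, controls_small)
    return model, model.fit()


def make_panel(
    wind: dict[str, np.ndarray],
    rate: dict[str, np.ndarray] | None = None,
    population: float = 1e5,
    t_start: int = 1,
    temperature: float = 15.0,
) -> StatePanel:
    """Hand-build a balanced panel from per-state wind (and rate) arrays.

    Months run t_start..t_start+n-1; rows with t < 1 get no outcomes.
    """
    n = len(next(iter(wind.values())))
    t = np.arange(t_start, t_start + n)
    frames = []
    for s, w in wind.items():
        r = rate[s] if rate is not None else np.zeros(n)
        df = pd.DataFrame(
            {
                "state": s,
                "t": t,
                "month": calendar_month(t),
                "wind": np.asarray(w, dtype=float),
                "temperature": temperature,
                "deaths": np.asarray(r, dtype=float) * population / 1e5,
                "population": population,
            }
        )
        df.loc[df["t"] < 1, ["deaths", "population"]] = np.nan
        frames.append(df)
    return StatePanel(pd.concat(frames, ignore_index=True))
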