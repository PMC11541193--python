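"""Mortality-burden accounting: from impulse responses to excess deaths.

Each storm-by-state event contributes a stream of excess deaths
``pop_{i,t+l}/1e5 * (response at lag l)`` over the months following
landfall; the response is the estimated linear marginal effect scaled by
the event's incidence, or a group-specific nonlinear per-event curve.
Streams superpose additively across storms into the national monthly
burden envelope, whose linear trend and counterfactual-population
variants decompose long-run changes into climatological, spatial and
demographic contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .panel import StatePanel

#: A response is either a per-m/s lag curve (array-like over lags
#: 0..horizon, scaled linearly by incidence) or a callable z -> lag curve
#: for one event of incidence z (the nonlinear dose path).
Response = "np.ndarray | pd.Series | Callable[[float], np.ndarray]"


class BurdenError(ValueError):
    pass


def _response_curve(response, z: float, horizon: int) -> np.ndarray:
    if callable(response):
        curve = np.asarray(response(z), dtype=float)
    else:
        arr = response.to_numpy() if isinstance(response, pd.Series) else np.asarray(response, dtype=float)
        if isinstance(response, pd.Series) and response.index.min() < 0:
            arr = response.loc[0:].to_numpy()
        curve = arr * z
    if len(curve) < horizon + 1:
        raise BurdenError(
            f"response covers {len(curve) - 1} lags but horizon is {horizon}"
        )
    return curve[: horizon + 1]


def storm_response(
    event,
    response,
    populations: pd.DataFrame,
    horizon: int = 172,
    truncate: bool = True,
) -> pd.Series:
    """Monthly excess-death stream (persons) for one storm-by-state event.

    ``event`` needs fields ``state``, ``t`` and ``incidence``;
    ``populations`` is a (t x state) person table.  Months beyond the
    population path are dropped when ``truncate`` is true, otherwise an
    error is raised.
    """
    state, t0, z = event["state"], int(event["t"]), float(event["incidence"])
    if z == 0:
        return pd.Series(dtype=float, name="deaths")
    curve = _response_curve(response, z, horizon)
    months = np.arange(t0, t0 + horizon + 1)
    pop = populations[state].reindex(months)
    if pop.isna().any() and not truncate:
        raise BurdenError(
            f"population path for {state} does not cover months "
            f"{months[pop.isna().to_numpy()][0]}..{months[-1]}; pass truncate=True"
        )
    deaths = pop.to_numpy() / 1e5 * curve
    out = pd.Series(deaths, index=pd.Index(months, name="t"), name="deaths")
    return out.dropna()


@dataclass
class BurdenResult:
    """Excess-death streams and their aggregates.

    ``streams`` is tidy (storm, state, t, deaths); ``national`` is the
    stacked monthly envelope, the exact sum of the per-storm streams.
    ``truncated_mass`` estimates the deaths pushed past the population
    path's end (final-month population held fixed as the stand-in path).
    """

    streams: pd.DataFrame
    national: pd.Series
    total: float
    n_storms: int
    per_storm_average: float
    by_state: pd.Series
    truncated_mass: float

    @property
    def trend(self) -> float:
        """OLS slope of the monthly national series (deaths per month)."""
        return national_trend(self.national)

    def monthly_mean(self) -> float:
        return float(self.national.mean())


def national_trend(series: pd.Series) -> float:
    if len(series) < 24:
        raise BurdenError("national series shorter than 24 months")
    t = series.index.to_numpy(dtype=float)
    return float(np.polyfit(t, series.to_numpy(), 1)[0])


def total_burden(
    events: pd.DataFrame,
    responses,
    populations: pd.DataFrame,
    horizon: int = 172,
    state_groups: Mapping | None = None,
    months: tuple[int, int] | None = None,
) -> BurdenResult:
    """Superpose all storm streams into the national burden (Fig.-3-style).

    ``responses`` is a single response (every state shares it) or a dict
    of group label -> response with ``state_groups`` mapping each state
    to its label (the risk-group assignment).  ``months`` restricts the
    reported envelope (default: the population path's span).
    """
    t_lo, t_hi = months if months else (int(populations.index.min()), int(populations.index.max()))
    index = pd.Index(np.arange(t_lo, t_hi + 1), name="t")
    national = pd.Series(0.0, index=index)
    rows = []
    truncated = 0.0
    pop_last = populations.iloc[-1]
    for ev in events.itertuples(index=False):
        event = {"state": ev.state, "t": ev.t, "incidence": ev.incidence}
        if state_groups is not None:
            label = state_groups.get(ev.state)
            if label not in responses:
                raise BurdenError(f"state {ev.state!r} has no response assignment")
            response = responses[label]
        elif isinstance(responses, dict):
            raise BurdenError("responses is a dict but state_groups was not given")
        else:
            response = responses
        stream = storm_response(event, response, populations, horizon, truncate=True)
        if len(stream) < horizon + 1 and event["incidence"] > 0:
            curve = _response_curve(response, event["incidence"], horizon)
            missing = curve[len(stream):]
            truncated += float(pop_last[ev.state] / 1e5 * missing.sum())
        stream = stream.loc[(stream.index >= t_lo) & (stream.index <= t_hi)]
        if stream.empty:
            continue
        national.loc[stream.index] += stream.to_numpy()
        rows.append(
            pd.DataFrame(
                {"storm_id": ev.storm_id, "state": ev.state, "t": stream.index, "deaths": stream.to_numpy()}
            )
        )
    streams = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["storm_id", "state", "t", "deaths"])
    )
    total = float(streams["deaths"].sum())
    n_storms = int(events["storm_id"].nunique()) if len(events) else 0
    by_state = (
        streams.groupby("state")["deaths"].sum()
        if len(streams)
        else pd.Series(dtype=float)
    )
    return BurdenResult(
        streams=streams,
        national=national,
        total=total,
        n_storms=n_storms,
        per_storm_average=total / n_storms if n_storms else 0.0,
        by_state=by_state,
        truncated_mass=truncated,
    )


def proportion_by_state(burden: BurdenResult, panel: StatePanel) -> pd.Series:
    """Share of each state's deaths attributable to storms:
    proportion_i = sum_t burden_it / sum_t deaths_it (NaN where a state
    records no deaths)."""
    obs = panel.df[panel.df["deaths"].notna()]
    deaths_by_state = obs.groupby("state")["deaths"].sum()
    burden_by_state = burden.by_state.reindex(deaths_by_state.index).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = burden_by_state / deaths_by_state
    prop[deaths_by_state == 0] = np.nan
    return prop.rename("proportion")


@dataclass
class PopulationScenario:
    """A (possibly counterfactual) population path for burden accounting."""

    kind: str                      # 'actual' | 'fixed_year' | 'deflated'
    path: pd.DataFrame             # (t x state) persons
    delta: float | None = None     # national growth fraction (deflated only)
    note: str = ""


def population_in_year(panel: StatePanel, year: int) -> pd.Series:
    """Per-state mean population over year ``year`` (months 12(y-1)+1..12y)."""
    lo, hi = 12 * (year - 1) + 1, 12 * year
    df = panel.df[(panel.df["t"] >= lo) & (panel.df["t"] <= hi) & panel.df["population"].notna()]
    if df.empty or df["t"].nunique() < hi - lo + 1:
        raise BurdenError(f"year {year} (months {lo}..{hi}) not fully present in panel")
    return df.groupby("state")["population"].mean()


def counterfactual_population(
    panel: StatePanel,
    kind: str = "actual",
    base_year: int | None = None,
    target_year: int | None = None,
) -> PopulationScenario:
    """Build an actual, frozen-year, or deflated population path.

    ``fixed_year`` freezes every state at its ``target_year`` level.
    ``deflated`` keeps the ``target_year`` spatial shares but rescales
    by 1/(1 + Delta), Delta = (total_target - total_base)/total_base, so
    the national total equals the ``base_year`` total.
    """
    lo, hi = panel.observed_t_range
    actual = panel.pivot("population").loc[lo:hi]
    if kind == "actual":
        return PopulationScenario("actual", actual)
    if kind == "fixed_year":
        if target_year is None:
            raise BurdenError("fixed_year scenario needs target_year")
        frozen = population_in_year(panel, target_year)
        path = pd.DataFrame(
            np.tile(frozen.reindex(actual.columns).to_numpy(), (len(actual), 1)),
            index=actual.index,
            columns=actual.columns,
        )
        return PopulationScenario("fixed_year", path, note=f"frozen at year {target_year}")
    if kind == "deflated":
        if base_year is None or target_year is None:
            raise BurdenError("deflated scenario needs base_year and target_year")
        pop_base = population_in_year(panel, base_year)
        pop_target = population_in_year(panel, target_year)
        delta = (pop_target.sum() - pop_base.sum()) / pop_base.sum()
        deflated = pop_target / (1.0 + delta)
        path = pd.DataFrame(
            np.tile(deflated.reindex(actual.columns).to_numpy(), (len(actual), 1)),
            index=actual.index,
            columns=actual.columns,
        )
        return PopulationScenario(
            "deflated", path, delta=float(delta),
            note=f"{target_year} shares at {base_year} national total",
        )
    raise BurdenError(f"unknown scenario kind {kind!r}")


def trend_decomposition(
    events: pd.DataFrame,
    responses,
    scenarios: Mapping[str, PopulationScenario],
    horizon: int = 172,
    state_groups: Mapping | None = None,
) -> pd.DataFrame:
    """Monthly burden trend per population scenario and all pairwise
    differences; the difference between two scenarios isolates the factor
    that distinguishes them (climate sequence, spatial shares, growth)."""
    if len(scenarios) < 2:
        raise BurdenError("need at least two scenarios to decompose")
    trends = {}
    for name, sc in scenarios.items():
        if len(sc.path) < 24:
            raise BurdenError(f"scenario {name!r} spans fewer than 24 months")
        res = total_burden(events, responses, sc.path, horizon, state_groups)
        trends[name] = {"trend": res.trend, "monthly_mean": res.monthly_mean(), "total": res.total}
    out = pd.DataFrame(trends).T
    names = list(scenarios)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out.loc[f"{a} - {b}", "trend"] = out.loc[a, "trend"] - out.loc[b, "trend"]
    return out
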