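"""Balanced state-by-month panel container and delimited-file I/O.

The panel is the single in-memory data contract shared by the estimator,
the randomization harness and the burden accounting.  Rows are indexed by
``(state, t)`` where ``t`` is a 1-based month-of-sample integer; rows with
``t < 1`` are exposure burn-in months that carry wind (and optionally
temperature) history but no outcome.  Units follow the conventions of the
underlying mortality-statistics literature: deaths are counts, population
is persons, wind is state-area-averaged maximum sustained wind in m/s,
and the derived ``mortality_rate`` is deaths per 100,000 per month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns, in canonical order, with a short unit note.
PANEL_COLUMNS = {
    "state": "state identifier (string or int)",
    "t": "month-of-sample index (int, 1-based; <=0 rows are burn-in)",
    "month": "calendar month 1-12",
    "wind": "TC incidence, m/s (0 in storm-free months)",
    "temperature": "mean temperature, degrees C",
    "deaths": "death count (may be NaN in burn-in rows)",
    "population": "persons (may be NaN in burn-in rows)",
}


class PanelError(ValueError):
    """Raised when a table fails the balanced-panel contract."""


def calendar_month(t: int | np.ndarray) -> int | np.ndarray:
    """Calendar month 1-12 for a month-of-sample index (works for t <= 0)."""
    return (np.asarray(t) - 1) % 12 + 1


@dataclass
class StatePanel:
    """A validated, balanced state-by-month panel.

    Parameters
    ----------
    df : DataFrame
        One row per (state, t), covering every combination in the
        rectangular range.  Extra columns (strata, region labels, pixel
        ids) are preserved untouched.
    """

    df: pd.DataFrame
    _states: np.ndarray = field(init=False, repr=False)
    _months: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.sort_values(["state", "t"], kind="mergesort").reset_index(drop=True)
        self._validate()
        self._states = np.asarray(sorted(self.df["state"].unique(), key=str))
        self._months = np.sort(self.df["t"].unique())

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise PanelError(f"panel is missing required columns: {missing}")
        df = self.df
        states = df["state"].unique()
        ts = np.sort(df["t"].unique())
        full = np.arange(ts.min(), ts.max() + 1)
        if not np.array_equal(ts, full):
            gaps = sorted(set(full) - set(ts))
            raise PanelError(f"month-of-sample index has gaps: {gaps[:10]}")
        counts = df.groupby("t", sort=True)["state"].agg(["count", "nunique"])
        bad_t = counts.index[(counts["count"] != len(states)) | (counts["nunique"] != len(states))]
        if len(bad_t):
            cells = []
            for t in bad_t[:5]:
                present = set(df.loc[df["t"] == t, "state"])
                cells += [(s, int(t)) for s in states if s not in present]
            raise PanelError(f"panel is unbalanced; missing (state, t) cells include: {cells[:10]}")
        if df.duplicated(["state", "t"]).any():
            dup = df[df.duplicated(["state", "t"])].iloc[0]
            raise PanelError(f"duplicate cell (state={dup['state']}, t={dup['t']})")
        m = df["month"].to_numpy()
        if ((m < 1) | (m > 12)).any():
            raise PanelError("calendar month outside 1..12")
        if df.groupby("t")["month"].nunique().max() > 1:
            raise PanelError("calendar month is not a function of month-of-sample")
        obs = df["deaths"].notna()
        if (df.loc[obs, "deaths"] < 0).any():
            rows = df.index[obs & (df["deaths"] < 0)][:5].tolist()
            raise PanelError(f"negative deaths at rows {rows}")
        pop_obs = df["population"].notna()
        if (df.loc[pop_obs, "population"] <= 0).any():
            raise PanelError("non-positive population")
        if (df["wind"].fillna(0) < 0).any():
            raise PanelError("negative wind incidence")

    # -- basic geometry ------------------------------------------------
    @property
    def states(self) -> np.ndarray:
        return self._states

    @property
    def n_states(self) -> int:
        return len(self._states)

    @property
    def t_range(self) -> tuple[int, int]:
        return int(self._months[0]), int(self._months[-1])

    @property
    def observed_t_range(self) -> tuple[int, int]:
        """Range of months that carry outcomes (deaths non-missing for all states)."""
        obs = self.df[self.df["deaths"].notna()].groupby("t")["state"].count()
        full = obs[obs == self.n_states]
        if full.empty:
            raise PanelError("panel has no fully observed months")
        return int(full.index.min()), int(full.index.max())

    # -- derived columns ----------------------------------------------
    def mortality_rate(self) -> pd.Series:
        """Deaths per 100,000 per month; NaN in burn-in rows."""
        return self.df["deaths"] / self.df["population"] * 1e5

    def pivot(self, column: str) -> pd.DataFrame:
        """Wide (t x state) layout of one column, sorted both ways."""
        return self.df.pivot(index="t", columns="state", values=column).sort_index()

    def wind_matrix(self) -> pd.DataFrame:
        return self.pivot("wind")

    def with_wind(self, wind: pd.DataFrame) -> "StatePanel":
        """Return a copy whose wind column is replaced from a (t x state) table."""
        long = wind.stack().rename("wind").reset_index()
        long.columns = ["t", "state", "wind"]
        df = self.df.drop(columns="wind").merge(long, on=["state", "t"], how="left")
        return StatePanel(df)

    # -- I/O -----------------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "StatePanel":
        """Read a comma-separated panel with a header row and validate it."""
        df = pd.read_csv(path)
        try:
            return cls(df)
        except PanelError as err:
            raise PanelError(f"{path}: {err}") from err

    def to_csv(self, path) -> None:
        cols = list(PANEL_COLUMNS) + [c for c in self.df.columns if c not in PANEL_COLUMNS]
        self.df.to_csv(path, index=False, columns=cols)

    def __len__(self) -> int:
        return len(self.df)
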