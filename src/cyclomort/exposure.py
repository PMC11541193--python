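"""Pixel-to-state wind aggregation and climatological risk grouping.

Storm winds are reconstructed on a pixel grid; the state-month exposure
used by the estimator is the mean over all of a state's pixels of the
per-pixel monthly maximum across storms (max-then-mean).  States are then
classified by their long-run mean incidence: the quartile of TC states
with the lowest non-zero mean forms the "low average incidence" group,
quartiles 2-4 pooled form the "high" group, and states with zero mean
are non-TC states outside the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import StatePanel


class ExposureError(ValueError):
    pass


def aggregate_pixels_to_state(
    pixel_winds: pd.DataFrame,
    pixel_membership: Mapping | pd.Series,
    months: np.ndarray | None = None,
    pixel_weights: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Collapse pixel-by-storm winds to a balanced (t x state) series.

    Parameters
    ----------
    pixel_winds : DataFrame with columns ``pixel, storm, t, wind``
        One row per (pixel, storm, month) with max sustained wind (m/s).
    pixel_membership : mapping pixel -> state
        Must cover every pixel in the table; defines each state's full
        pixel roster, so pixels untouched in a month still enter the
        mean with wind 0.
    months : optional explicit month index for the output (defaults to
        the range spanned by the table).
    pixel_weights : optional per-pixel weights (e.g. latitude-area
        correction); equal weights by default.

    Rule: per (pixel, month) take the max over storms; per (state,
    month) take the (weighted) mean over the state's pixels; months with
    no storms are 0.
    """
    req = {"pixel", "storm", "t", "wind"}
    if not req.issubset(pixel_winds.columns):
        raise ExposureError(f"pixel table needs columns {sorted(req)}")
    if (pixel_winds["wind"] < 0).any():
        raise ExposureError("negative wind in pixel table")
    membership = pd.Series(dict(pixel_membership) if not isinstance(pixel_membership, pd.Series) else pixel_membership)
    unknown = set(pixel_winds["pixel"]) - set(membership.index)
    if unknown:
        raise ExposureError(f"pixels with unknown state: {sorted(unknown)[:10]}")
    weights = (
        pd.Series(1.0, index=membership.index)
        if pixel_weights is None
        else pd.Series(dict(pixel_weights) if not isinstance(pixel_weights, pd.Series) else pixel_weights).reindex(membership.index)
    )
    if weights.isna().any() or (weights <= 0).any():
        raise ExposureError("pixel weights must be positive and cover all pixels")

    if months is None:
        months = np.arange(pixel_winds["t"].min(), pixel_winds["t"].max() + 1)
    states = sorted(membership.unique(), key=str)
    out = pd.DataFrame(0.0, index=pd.Index(months, name="t"), columns=pd.Index(states, name="state"))

    pix_month = pixel_winds.groupby(["pixel", "t"])["wind"].max().reset_index()
    pix_month["state"] = pix_month["pixel"].map(membership)
    pix_month["w"] = pix_month["pixel"].map(weights)
    total_w = weights.groupby(membership).sum()
    sums = (
        (pix_month["wind"] * pix_month["w"])
        .groupby([pix_month["state"], pix_month["t"]])
        .sum()
    )
    for (s, t), v in sums.items():
        out.loc[t, s] = v / total_w[s]
    return out


@dataclass
class RiskGroups:
    """Per-state long-run incidence and the low/high risk partition."""

    mean_incidence: pd.Series       # m/s, indexed by state
    quartile: pd.Series             # 1..4 for TC states, <NA> for non-TC
    label: pd.Series                # 'low' / 'high' / 'non_tc'

    @property
    def tc_states(self) -> list:
        return list(self.mean_incidence.index[self.mean_incidence > 0])

    @property
    def low_states(self) -> list:
        return list(self.label.index[self.label == "low"])

    @property
    def high_states(self) -> list:
        return list(self.label.index[self.label == "high"])

    @classmethod
    def from_panel(cls, panel: StatePanel) -> "RiskGroups":
        obs_lo, obs_hi = panel.observed_t_range
        wind = panel.wind_matrix().loc[obs_lo:obs_hi]
        return cls.from_wind(wind)

    @classmethod
    def from_wind(cls, wind: pd.DataFrame) -> "RiskGroups":
        """Classify from a (t x state) wind table: mean = sum_t wind / T."""
        means = wind.mean(axis=0).sort_index(key=lambda ix: ix.map(str))
        nz = means[means > 0]
        if len(nz) < 4:
            raise ExposureError(
                f"only {len(nz)} states with non-zero incidence; quartiles undefined"
            )
        cuts = np.quantile(nz.to_numpy(), [0.25, 0.5, 0.75])
        # inclusive lower bound: a mean exactly at a cut goes to the lower quartile
        quart = pd.Series(pd.NA, index=means.index, dtype="Int64")
        for s, m in nz.items():
            quart.loc[s] = int(1 + np.sum(m > cuts))
        label = pd.Series("non_tc", index=means.index)
        label[quart == 1] = "low"
        label[quart > 1] = "high"
        return cls(mean_incidence=means, quartile=quart, label=label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_incidence": self.mean_incidence, "quartile": self.quartile, "label": self.label}
        )
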