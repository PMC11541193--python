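"""Group-interacted and nonlinear distributed-lag models.

Heterogeneous responses are estimated by interacting the exposure lag
block with group indicators while keeping the control blocks common to
all groups.  Groups may partition states (risk quartiles, coastal-share
splits) or time (era splits, where exposure is attributed to the storm's
landfall era).  The nonlinear variant lets the impulse response be a
cubic polynomial in wind incidence, separately for low- and high-risk
states, with powers of wind computed on the raw monthly series before
lag expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .exposure import RiskGroups
from .model import (
    ControlSpec,
    CumulativeResponse,
    DistributedLagModel,
    LagSpec,
    cumulative_response,
)
from .panel import StatePanel


class GroupError(ValueError):
    pass


def _component_winds_by_state(
    wind: pd.DataFrame, groups: Mapping
) -> dict[str, pd.DataFrame]:
    """Mask the wind table into one component per group of states."""
    labels: dict[str, list] = {}
    for s in wind.columns:
        if s not in groups:
            raise GroupError(f"state {s!r} has no group assignment")
        labels.setdefault(str(groups[s]), []).append(s)
    comps = {}
    for lab in sorted(labels):
        masked = wind.copy()
        masked.loc[:, [s for s in wind.columns if s not in labels[lab]]] = 0.0
        comps[lab] = masked
    return comps


def _component_winds_by_era(
    wind: pd.DataFrame, cutoffs: list[int], labels: list[str] | None
) -> dict[str, pd.DataFrame]:
    """Split the wind series in time; exposure stays attributed to the
    month the storm struck, so lag columns inherit the storm's era."""
    edges = [-np.inf] + sorted(cutoffs) + [np.inf]
    n = len(edges) - 1
    labels = labels or [f"era{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise GroupError("need one label per era")
    t = wind.index.to_numpy()
    comps = {}
    for i, lab in enumerate(labels):
        mask = (t > edges[i]) & (t <= edges[i + 1])
        masked = wind.copy()
        masked.loc[~mask, :] = 0.0
        comps[lab] = masked
    return comps


class _InteractedLagModel:
    """Shared machinery: concatenated lag blocks over component winds,
    common controls, one OLS solve."""

    def __init__(
        self,
        panel: StatePanel,
        components: dict[str, pd.DataFrame],
        lags: LagSpec | None,
        controls: ControlSpec | None,
        edge: str = "strict",
    ) -> None:
        self.panel = panel
        self.components = components
        self.base = DistributedLagModel(panel, lags, controls, edge)

    def _fit_core(self):
        d, proj, yres = self.base._prepare()
        blocks, names, spans = [], [], {}
        pos = 0
        for lab, wind in self.components.items():
            Xb = self.base.lag_block(wind)
            if np.linalg.norm(Xb) == 0:
                raise GroupError(f"group {lab!r} has no exposure variation")
            blocks.append(Xb)
            names += [f"{lab}:{nm}" for nm in d.exposure_names]
            spans[lab] = slice(pos, pos + Xb.shape[1])
            pos += Xb.shape[1]
        X = np.hstack(blocks)
        if d.weights is not None:
            X = X * np.sqrt(d.weights)[:, None]
        Xres = proj.residualize(X)
        res = self.base._solve(d, proj, Xres, yres, extra_names=names)
        return res, spans


@dataclass
class GroupedLagResults:
    """Per-group lag coefficients with a cross-group equality test."""

    labels: list[str]
    lag_values: np.ndarray
    params: np.ndarray
    vcov: np.ndarray
    spans: dict[str, slice]
    nobs: int
    dof_resid: int
    sigma2: float
    rsquared: float
    lagspec: LagSpec

    def beta(self, group: str) -> pd.Series:
        return pd.Series(
            self.params[self.spans[group]],
            index=pd.Index(self.lag_values, name="lag"),
            name=group,
        )

    def cumulative(self, group: str, horizon: int | None = None) -> CumulativeResponse:
        horizon = horizon if horizon is not None else self.lagspec.cumulative_horizon
        sl = self.spans[group]
        return cumulative_response(
            self.lag_values, self.params[sl], self.vcov[sl, sl], horizon, dof=self.dof_resid
        )

    def equality_test(
        self, lag_range: tuple[int, int] | None = None
    ) -> tuple[float, tuple[int, int], float]:
        """Two-sided F-test that all groups share the same lag
        coefficients over ``lag_range`` (default: all positive lags)."""
        if len(self.labels) < 2:
            raise GroupError("equality test needs at least two groups")
        lo, hi = lag_range or (1, int(self.lag_values.max()))
        sel = np.nonzero((self.lag_values >= lo) & (self.lag_values <= hi))[0]
        ref = self.labels[0]
        rows = []
        k = len(self.params)
        for lab in self.labels[1:]:
            for j in sel:
                r = np.zeros(k)
                r[self.spans[lab].start + j] = 1.0
                r[self.spans[ref].start + j] = -1.0
                rows.append(r)
        R = np.vstack(rows)
        rb = R @ self.params
        RVR = R @ self.vcov @ R.T
        q = len(rows)
        stat = float(rb @ np.linalg.solve(RVR, rb)) / q
        p = float(scipy.stats.f.sf(stat, q, self.dof_resid))
        return stat, (q, self.dof_resid), p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({lab: self.beta(lab) for lab in self.labels})


class GroupedLagModel(_InteractedLagModel):
    """Distributed-lag model with group-specific impulse responses.

    ``groups`` maps each state to a group label; every state must be
    assigned.  Controls are never interacted, matching the convention
    that only the exposure response differs by group.  A single group
    reproduces the pooled model exactly.
    """

    def __init__(
        self,
        panel: StatePanel,
        groups: Mapping,
        lags: LagSpec | None = None,
        controls: ControlSpec | None = None,
        edge: str = "strict",
    ) -> None:
        if isinstance(groups, pd.Series):
            groups = groups.to_dict()
        wind = panel.wind_matrix()
        comps = _component_winds_by_state(wind, groups)
        super().__init__(panel, comps, lags, controls, edge)

    @classmethod
    def era_split(
        cls,
        panel: StatePanel,
        cutoffs: int | list[int],
        labels: list[str] | None = None,
        lags: LagSpec | None = None,
        controls: ControlSpec | None = None,
        edge: str = "strict",
    ) -> "GroupedLagModel":
        """Split exposure by storm date: did earlier storms have a
        different impact than later ones?"""
        obj = cls.__new__(cls)
        if isinstance(cutoffs, int):
            cutoffs = [cutoffs]
        comps = _component_winds_by_era(
            panel.wind_matrix(), cutoffs, labels or (["early", "late"] if len(cutoffs) == 1 else None)
        )
        _InteractedLagModel.__init__(obj, panel, comps, lags, controls, edge)
        return obj

    def fit(self) -> GroupedLagResults:
        res, spans = self._fit_core()
        return GroupedLagResults(
            labels=list(self.components),
            lag_values=res.design.lag_values,
            params=res.params,
            vcov=res.vcov,
            spans=spans,
            nobs=res.nobs,
            dof_resid=res.dof_resid,
            sigma2=res.sigma2,
            rsquared=res.rsquared,
            lagspec=self.base.lags,
        )


@dataclass
class NonlinearLagResults:
    """Cubic-in-incidence impulse responses by risk group.

    ``theta(group, r)`` are the lag coefficients on wind**r; the
    cumulative dose-response at wind level w is
    ``Omega_g(w) = sum_r (sum_{l=0..H} theta_{r,l}) * w**r``, which is 0
    at w = 0 for every group by construction.
    """

    labels: list[str]
    powers: list[int]
    lag_values: np.ndarray
    params: np.ndarray
    vcov: np.ndarray
    spans: dict[tuple[str, int], slice]
    nobs: int
    dof_resid: int
    sigma2: float
    lagspec: LagSpec

    def theta(self, group: str, power: int) -> pd.Series:
        return pd.Series(
            self.params[self.spans[(group, power)]],
            index=pd.Index(self.lag_values, name="lag"),
            name=f"{group}:w^{power}",
        )

    def marginal_response(self, group: str, z: float) -> pd.Series:
        """d(rate)/d(impulse of size z) per lag: sum_r theta_{r,l} z^r,
        i.e. the per-event response curve at incidence z (not per m/s)."""
        out = None
        for r in self.powers:
            term = self.theta(group, r) * z**r
            out = term if out is None else out + term
        return out

    def cumulative_dose(
        self, group: str, w: float, horizon: int | None = None
    ) -> tuple[float, float]:
        """Cumulative excess mortality per 100,000 from one event of
        incidence ``w`` m/s, with delta-method SE."""
        horizon = horizon if horizon is not None else self.lagspec.cumulative_horizon
        lag_sel = (self.lag_values >= 0) & (self.lag_values <= horizon)
        grad = np.zeros(len(self.params))
        val = 0.0
        for r in self.powers:
            sl = self.spans[(group, r)]
            idx = np.arange(sl.start, sl.stop)[lag_sel]
            val += float(self.params[idx].sum()) * w**r
            grad[idx] = w**r
        var = float(grad @ self.vcov @ grad)
        return val, np.sqrt(max(var, 0.0))

    def dose_response(
        self, group: str, w_grid, horizon: int | None = None
    ) -> pd.DataFrame:
        rows = [self.cumulative_dose(group, float(w), horizon) for w in w_grid]
        est, se = zip(*rows)
        return pd.DataFrame({"wind": list(w_grid), "omega": est, "se": se})


class NonlinearLagModel(_InteractedLagModel):
    """Impulse response cubic in incidence, by low/high risk group.

    Powers of wind are computed on the raw monthly state series before
    lag expansion; only TC states (non-zero mean incidence) carry
    exposure terms.  ``degree`` must be 1, 2 or 3; degree 1 with a
    single group nests the baseline linear model.
    """

    def __init__(
        self,
        panel: StatePanel,
        risk: RiskGroups | Mapping,
        lags: LagSpec | None = None,
        controls: ControlSpec | None = None,
        degree: int = 3,
        edge: str = "strict",
    ) -> None:
        if degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        self.degree = degree
        if isinstance(risk, RiskGroups):
            mapping = {
                s: lab for s, lab in risk.label.items() if lab in ("low", "high")
            }
        else:
            mapping = dict(risk)
        wind = panel.wind_matrix()
        assigned = {s: mapping.get(s, "__none__") for s in wind.columns}
        by_state = _component_winds_by_state(wind, assigned)
        by_state.pop("__none__", None)
        comps: dict[str, pd.DataFrame] = {}
        for lab, wmat in by_state.items():
            for r in range(1, degree + 1):
                comps[f"{lab}^({r})"] = wmat**r
        super().__init__(panel, comps, lags, controls, edge)
        self._group_labels = sorted(by_state)

    def fit(self) -> NonlinearLagResults:
        res, raw_spans = self._fit_core()
        spans = {}
        for key, sl in raw_spans.items():
            lab, r = key.rsplit("^(", 1)
            spans[(lab, int(r[:-1]))] = sl
        return NonlinearLagResults(
            labels=self._group_labels,
            powers=list(range(1, self.degree + 1)),
            lag_values=res.design.lag_values,
            params=res.params,
            vcov=res.vcov,
            spans=spans,
            nobs=res.nobs,
            dof_resid=res.dof_resid,
            sigma2=res.sigma2,
            lagspec=self.base.lags,
        )
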