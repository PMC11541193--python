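"""Distributed-lag deconvolution of mortality impulse responses.

The model regresses the monthly state mortality rate (deaths per 100,000)
on current, lagged and led tropical-cyclone wind incidence plus a rich
control set, recovering the characteristic per-m/s impulse-response
function beta_l shared by all storms::

    rate_{it} = sum_{l=-L..K} beta_l * wind_{i,t-l}
              + state-by-calendar-month effects (+ linear trends)
              + state polynomial trends + national month effects
              + state-specific quadratic temperature + eps_{it}

solved by OLS with the fixed-effect families absorbed (Frisch-Waugh)
rather than materialized as dummies.  Lead coefficients (l < 0) act as
negative exposure controls: future storms must not predict current
mortality in a well-specified model.

The fitted object follows the statsmodels convention: a
:class:`DistributedLagModel` built from a panel, whose :meth:`fit`
returns a :class:`DistributedLagResults` carrying coefficients,
classical covariance, residuals and derived summaries (cumulative
response, quadratic IRF approximation, residual diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .absorb import AbsorptionGroup, ControlProjector, RankError, fe_union_rank
from .panel import StatePanel


class EdgePolicyError(ValueError):
    """Raised when the requested lag window exceeds the available history."""


@dataclass
class LagSpec:
    """Lead/lag window of the exposure block.

    ``n_leads`` future-exposure (falsification) terms, ``n_lags`` past
    months, and the default horizon at which cumulative responses are
    reported.
    """

    n_leads: int = 72
    n_lags: int = 240
    cumulative_horizon: int = 172

    def __post_init__(self) -> None:
        if self.n_leads < 0 or self.n_lags < 1:
            raise ValueError("need n_leads >= 0 and n_lags >= 1")
        if self.cumulative_horizon > self.n_lags:
            raise ValueError("cumulative_horizon cannot exceed n_lags")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.n_leads, self.n_lags + 1)


@dataclass
class ControlSpec:
    """Which control blocks enter the regression.

    Defaults reproduce the full baseline specification: state-by-calendar
    -month fixed effects, state-by-calendar-month linear trends, national
    month-of-sample fixed effects, state-specific time polynomials of
    order 8 (in time rescaled to [0, 1]) and state-specific quadratic
    temperature.  ``state_fe`` provides a plain state fixed effect for
    reduced specifications; ``region_month_fe`` interacts the
    month-of-sample effects with a ``region`` column; ``weights`` names a
    regression-weight column (e.g. population).
    """

    state_month_fe: bool = True
    month_of_sample_fe: bool = True
    state_trend_order: int = 8
    state_seasonal_trend: bool = True
    state_temperature: bool = True
    state_fe: bool = False
    region_month_fe: bool = False
    weights: str | None = None
    cluster: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.state_trend_order <= 8:
            raise ValueError("state_trend_order must be in 0..8")
        if self.state_seasonal_trend and not self.state_month_fe:
            raise ValueError("state_seasonal_trend requires state_month_fe")


@dataclass
class DesignInfo:
    """Echo of the built design: sample, labels, fixed-effect structure."""

    states: np.ndarray
    est_months: np.ndarray
    lag_values: np.ndarray
    exposure: np.ndarray                       # (n, k)
    exposure_names: list[str]
    y: np.ndarray
    groups: list[AbsorptionGroup]
    continuous: np.ndarray
    continuous_names: list[str]
    fe_rank: int
    non_identified: list[str]
    reference_note: str
    weights: np.ndarray | None
    edge: str
    row_state: np.ndarray
    row_t: np.ndarray

    @property
    def nobs(self) -> int:
        return len(self.y)


def _lag_name(l: int) -> str:
    return f"wind[l={l:+d}]" if l < 0 else f"wind[l={l}]"


class DistributedLagModel:
    """Distributed-lag panel OLS of mortality rate on wind incidence.

    Parameters
    ----------
    panel : StatePanel
        Balanced panel; burn-in rows (t < 1) supply lag history.
    lags : LagSpec
    controls : ControlSpec
    edge : {"strict", "zero_pad"}
        "strict" keeps only outcome months with a complete lag history
        and complete lead future; "zero_pad" keeps all outcome months
        and treats out-of-window exposure as zero.
    """

    def __init__(
        self,
        panel: StatePanel,
        lags: LagSpec | None = None,
        controls: ControlSpec | None = None,
        edge: str = "strict",
    ) -> None:
        if edge not in ("strict", "zero_pad"):
            raise ValueError("edge must be 'strict' or 'zero_pad'")
        self.panel = panel
        self.lags = lags or LagSpec()
        self.controls = controls or ControlSpec()
        self.edge = edge
        self._design: DesignInfo | None = None
        self._projector: ControlProjector | None = None
        self._yres: np.ndarray | None = None

    # -- design construction ------------------------------------------
    def build_design(self) -> DesignInfo:
        """Assemble exposure columns, fixed-effect structure and controls."""
        if self._design is not None:
            return self._design
        panel, lg, ct = self.panel, self.lags, self.controls
        t_min, t_max = panel.t_range
        o_min, o_max = panel.observed_t_range
        if self.edge == "strict":
            lo = max(o_min, t_min + lg.n_lags)
            hi = min(o_max, t_max - lg.n_leads)
            if lo > hi:
                raise EdgePolicyError(
                    f"no outcome month has {lg.n_lags} lag months and {lg.n_leads} "
                    f"lead months of exposure history (wind spans t={t_min}..{t_max}, "
                    f"outcomes t={o_min}..{o_max}); shorten the window, extend the "
                    "burn-in, or use edge='zero_pad'"
                )
        else:
            lo, hi = o_min, o_max
        est_months = np.arange(lo, hi + 1)
        T_e = len(est_months)
        states = panel.states
        S = len(states)

        wind = panel.wind_matrix()
        rate = panel.pivot("deaths") / panel.pivot("population") * 1e5
        temp = panel.pivot("temperature")
        w_t = wind.index.to_numpy()
        pos = est_months - w_t[0]

        lag_values = lg.lags
        k = len(lag_values)
        idx = pos[:, None] - lag_values[None, :]          # (T_e, k) positions
        valid = (idx >= 0) & (idx < len(w_t))
        idx_c = np.clip(idx, 0, len(w_t) - 1)

        n = S * T_e
        X = np.empty((n, k))
        y = np.empty(n)
        row_state = np.empty(n, dtype=int)
        row_t = np.tile(est_months, S)
        for j, s in enumerate(states):
            sl = slice(j * T_e, (j + 1) * T_e)
            w = wind[s].to_numpy()
            X[sl] = np.where(valid, w[idx_c], 0.0)
            y[sl] = rate[s].reindex(est_months).to_numpy()
            row_state[sl] = j
        if np.isnan(y).any():
            raise EdgePolicyError("estimation window contains months without outcomes")

        cal = (row_t - 1) % 12                            # 0..11
        x_scaled = (row_t - o_min) / max(o_max - o_min, 1)

        # fixed-effect families
        groups: list[AbsorptionGroup] = []
        n_state_cells = cells_per_state = 0
        with_trend = False
        if ct.state_month_fe:
            codes = row_state * 12 + cal
            regs = (
                np.column_stack([np.ones(n), x_scaled])
                if ct.state_seasonal_trend
                else np.ones((n, 1))
            )
            with_trend = ct.state_seasonal_trend
            groups.append(AbsorptionGroup(codes, regs, "state_x_calmonth"))
            n_state_cells, cells_per_state = S * 12, 12
        elif ct.state_fe:
            groups.append(AbsorptionGroup(row_state, np.ones((n, 1)), "state"))
            n_state_cells, cells_per_state = S, 1

        n_regions = 0
        n_time_cells = 0
        if ct.month_of_sample_fe:
            if ct.region_month_fe:
                if "region" not in panel.df.columns:
                    raise ValueError("region_month_fe requires a 'region' column")
                reg_by_state = (
                    panel.df.drop_duplicates("state").set_index("state")["region"]
                )
                reg_labels = sorted(reg_by_state.unique(), key=str)
                reg_idx = reg_by_state.map({r: i for i, r in enumerate(reg_labels)})
                row_region = reg_idx.loc[states[row_state]].to_numpy()
                n_regions = len(reg_labels)
            else:
                row_region = np.zeros(n, dtype=int)
                n_regions = 1
            t_codes = row_region * T_e + (row_t - lo)
            groups.append(AbsorptionGroup(t_codes, np.ones((n, 1)), "month_of_sample"))
            n_time_cells = n_regions * T_e

        fe_rank = fe_union_rank(
            n_state_cells, cells_per_state, with_trend, n_time_cells, n_regions
        )

        # continuous controls (block-diagonal by state)
        cont_cols: list[np.ndarray] = []
        cont_names: list[str] = []
        if not groups:
            cont_cols.append(np.ones(n))
            cont_names.append("intercept")
        if ct.state_trend_order:
            for j, s in enumerate(states):
                mask = row_state == j
                for p in range(1, ct.state_trend_order + 1):
                    col = np.where(mask, x_scaled**p, 0.0)
                    cont_cols.append(col)
                    cont_names.append(f"trend[{s},t^{p}]")
        if ct.state_temperature:
            tv = np.empty(n)
            for j, s in enumerate(states):
                tv[j * T_e : (j + 1) * T_e] = temp[s].reindex(est_months).to_numpy()
            if np.isnan(tv).any():
                raise ValueError("temperature missing in estimation window")
            for j, s in enumerate(states):
                mask = row_state == j
                cont_cols.append(np.where(mask, tv, 0.0))
                cont_names.append(f"temp[{s}]")
                cont_cols.append(np.where(mask, tv**2, 0.0))
                cont_names.append(f"temp2[{s}]")
        continuous = (
            np.column_stack(cont_cols) if cont_cols else np.empty((n, 0))
        )

        weights = None
        if ct.weights is not None:
            wdf = panel.df.set_index(["state", "t"])[ct.weights]
            weights = np.array(
                [wdf.loc[(states[row_state[i]], row_t[i])] for i in range(n)], dtype=float
            )
            if (weights <= 0).any():
                raise ValueError("weights must be positive")

        names = [_lag_name(l) for l in lag_values]
        norms = np.linalg.norm(X, axis=0)
        non_identified = [names[j] for j in np.nonzero(norms == 0)[0]]
        ref_note = (
            "reference categories: fixed-effect families absorbed (first level "
            "implicit); collinear continuous columns dropped at fit time"
        )
        self._design = DesignInfo(
            states=states,
            est_months=est_months,
            lag_values=lag_values,
            exposure=X,
            exposure_names=names,
            y=y,
            groups=groups,
            continuous=continuous,
            continuous_names=cont_names,
            fe_rank=fe_rank,
            non_identified=non_identified,
            reference_note=ref_note,
            weights=weights,
            edge=self.edge,
            row_state=row_state,
            row_t=row_t,
        )
        return self._design

    # -- fitting -------------------------------------------------------
    def _prepare(self) -> tuple[DesignInfo, ControlProjector, np.ndarray]:
        d = self.build_design()
        if self._projector is None:
            sw = None if d.weights is None else np.sqrt(d.weights)
            groups = d.groups
            cont = d.continuous
            if sw is not None:
                groups = [
                    AbsorptionGroup(g.codes, g.Z * sw[:, None], g.name) for g in d.groups
                ]
                cont = cont * sw[:, None]
            self._projector = ControlProjector(groups, cont, list(d.continuous_names))
            yw = d.y if sw is None else d.y * sw
            self._yres = self._projector.residualize(yw)
        return d, self._projector, self._yres

    def fit(self) -> "DistributedLagResults":
        """Estimate the model by (weighted) least squares."""
        d, proj, yres = self._prepare()
        Xw = d.exposure if d.weights is None else d.exposure * np.sqrt(d.weights)[:, None]
        Xres = proj.residualize(Xw)
        return self._solve(d, proj, Xres, yres)

    def lag_block(self, wind: pd.DataFrame) -> np.ndarray:
        """Unweighted lead/lag exposure columns built from a (t x state)
        wind table, row-aligned with the estimation sample."""
        d = self.build_design()
        w_t = wind.index.to_numpy()
        lag_values = d.lag_values
        idx = (d.est_months - w_t[0])[:, None] - lag_values[None, :]
        valid = (idx >= 0) & (idx < len(w_t))
        idx_c = np.clip(idx, 0, len(w_t) - 1)
        T_e = len(d.est_months)
        X = np.empty((len(d.y), len(lag_values)))
        for j, s in enumerate(d.states):
            w = wind[s].to_numpy()
            X[j * T_e : (j + 1) * T_e] = np.where(valid, w[idx_c], 0.0)
        return X

    def fit_with_exposure(self, wind: pd.DataFrame) -> "DistributedLagResults":
        """Re-fit with a replacement (t x state) wind series, reusing the
        cached control projection (the placebo-randomization fast path)."""
        d, proj, yres = self._prepare()
        X = self.lag_block(wind)
        if d.weights is not None:
            X = X * np.sqrt(d.weights)[:, None]
        Xres = proj.residualize(X)
        return self._solve(d, proj, Xres, yres)

    def _solve(
        self,
        d: DesignInfo,
        proj: ControlProjector,
        Xres: np.ndarray,
        yres: np.ndarray,
        extra_names: list[str] | None = None,
    ) -> "DistributedLagResults":
        names = extra_names or d.exposure_names
        n, k = Xres.shape
        Q, R, piv = scipy.linalg.qr(Xres, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        if k and (diag[0] == 0 or np.any(diag < 1e-10 * diag[0])):
            rank = int(np.sum(diag > 1e-10 * diag[0])) if diag[0] > 0 else 0
            bad = [names[j] for j in piv[rank:]]
            hint = f" (design flagged non-identified: {d.non_identified})" if d.non_identified else ""
            raise RankError(f"exposure block rank deficient; offending columns: {bad}{hint}")
        beta_p = scipy.linalg.solve_triangular(R, Q.T @ yres)
        beta = np.empty(k)
        beta[piv] = beta_p
        Rinv = scipy.linalg.solve_triangular(R, np.eye(k))
        xtx_inv = np.empty((k, k))
        xtx_inv[np.ix_(piv, piv)] = Rinv @ Rinv.T
        resid = yres - Xres @ beta

        n_params = k + d.fe_rank + proj.rank_continuous
        dof = n - n_params
        if dof <= 0:
            raise RankError(f"non-positive residual dof ({dof})")
        ssr = float(resid @ resid)
        sigma2 = ssr / dof
        vcov = sigma2 * xtx_inv

        yw = d.y if d.weights is None else d.y * np.sqrt(d.weights)
        sst = float(np.sum((yw - yw.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof if sst > 0 else 0.0

        return DistributedLagResults(
            model=self,
            design=d,
            param_names=names,
            params=beta,
            vcov=vcov,
            resid=resid,
            nobs=n,
            dof_resid=dof,
            n_params=n_params,
            sigma2=sigma2,
            rsquared=r2,
            rsquared_adj=r2_adj,
            dropped_controls=list(proj.dropped),
        )


# ---------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------


@dataclass
class CumulativeResponse:
    """Cumulative excess mortality Omega_l per m/s with propagated SEs.

    ``omega[l] = sum_{k=0..l} beta_k`` for l >= 0, normalized so
    ``omega[-1] = 0``; leads are reverse-cumulated
    (``omega[l] = -sum_{k=l+1..-1} beta_k`` for l <= -2) so the
    difference identity ``omega[l] - omega[l-1] = beta_l`` holds at every
    lag.  Variances sum the full covariance block of the involved
    coefficients.
    """

    omega: pd.Series
    se: pd.Series
    horizon: int
    conf_level: float = 0.95
    dof: int | None = None

    def conf_int(self) -> pd.DataFrame:
        q = (
            scipy.stats.t.ppf(0.5 + self.conf_level / 2, self.dof)
            if self.dof
            else scipy.stats.norm.ppf(0.5 + self.conf_level / 2)
        )
        return pd.DataFrame(
            {"lower": self.omega - q * self.se, "upper": self.omega + q * self.se}
        )

    def at(self, lag: int) -> tuple[float, float]:
        return float(self.omega.loc[lag]), float(self.se.loc[lag])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"omega": self.omega, "se": self.se})
        ci = self.conf_int()
        return out.join(ci)


def cumulative_response(
    lag_values: np.ndarray,
    beta: np.ndarray,
    vcov: np.ndarray,
    horizon: int,
    conf_level: float = 0.95,
    dof: int | None = None,
) -> CumulativeResponse:
    """Cumulate a coefficient vector over its lag grid with full
    covariance propagation: Var(Omega_l) = 1' V_{0..l} 1."""
    keep = lag_values <= horizon
    lag_grid = lag_values[keep]
    b = np.asarray(beta)[keep]
    V = np.asarray(vcov)[np.ix_(keep, keep)]
    zero_pos = int(np.searchsorted(lag_grid, 0))
    omega = np.empty(len(lag_grid))
    var = np.empty(len(lag_grid))
    omega[zero_pos:] = np.cumsum(b[zero_pos:])
    # leads: omega_l = -sum_{k=l+1..-1} beta_k (reverse-cumulated,
    # excluding beta_l itself so that omega_{-1} = 0 and the difference
    # identity omega_l - omega_{l-1} = beta_l holds at negative lags too)
    if zero_pos:
        c = np.cumsum(b[:zero_pos][::-1])
        omega[:zero_pos] = -np.concatenate([[0.0], c[:-1]])[::-1]
    # block variance sums via 2-D cumulative sums of the covariance
    B = V.cumsum(axis=0).cumsum(axis=1)

    def block(a: int, c: int) -> float:  # inclusive index block sum
        tot = B[c, c]
        if a > 0:
            tot = tot - B[a - 1, c] - B[c, a - 1] + B[a - 1, a - 1]
        return float(tot)

    for i in range(len(lag_grid)):
        if lag_grid[i] >= 0:
            var[i] = block(zero_pos, i)
        elif lag_grid[i] == -1:
            var[i] = 0.0
        else:
            var[i] = block(i + 1, zero_pos - 1)
    idx = pd.Index(lag_grid, name="lag")
    omega_s = pd.Series(omega, index=idx, name="omega")
    se_s = pd.Series(np.sqrt(np.maximum(var, 0.0)), index=idx, name="se")
    if -1 in idx:
        omega_s.loc[-1] = 0.0
        se_s.loc[-1] = 0.0
    return CumulativeResponse(
        omega=omega_s, se=se_s, horizon=horizon, conf_level=conf_level, dof=dof
    )


@dataclass
class QuadraticFit:
    """Least-squares quadratic summary of the IRF over a lag range.

    ``peak_month = -a1 / (2 a2)`` and the value there are reported only
    when the parabola opens downward and the vertex lies inside the
    fitted range.
    """

    a0: float
    a1: float
    a2: float
    lag_range: tuple[int, int]
    peak_month: float | None = field(default=None)
    peak_value: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.a2 < 0:
            vertex = -self.a1 / (2.0 * self.a2)
            if self.lag_range[0] <= vertex <= self.lag_range[1]:
                self.peak_month = vertex
                self.peak_value = self(vertex)

    def __call__(self, x):
        return self.a0 + self.a1 * np.asarray(x) + self.a2 * np.asarray(x) ** 2

    @classmethod
    def from_beta(cls, beta: pd.Series, lag_range: tuple[int, int] = (0, 172)) -> "QuadraticFit":
        lo, hi = lag_range
        if hi - lo < 2:
            raise ValueError("need at least 3 lags for a quadratic fit")
        sel = beta.loc[lo:hi]
        c = np.polynomial.polynomial.polyfit(sel.index.to_numpy(float), sel.to_numpy(), 2)
        return cls(float(c[0]), float(c[1]), float(c[2]), lag_range)

    @classmethod
    def from_coefficients(
        cls, a0: float, a1: float, a2: float, lag_range: tuple[int, int] = (0, 172)
    ) -> "QuadraticFit":
        return cls(a0, a1, a2, lag_range)


@dataclass
class ResidualDiagnostics:
    """Distributional and serial-dependence summary of fit residuals."""

    skewness: float
    excess_kurtosis: float
    sd: float
    per_period_sd: pd.Series
    autocorrelations: pd.Series        # lags 1..12, NaN when undefined
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["skewness", "excess_kurtosis", "sd"],
                "value": [self.skewness, self.excess_kurtosis, self.sd],
            }
        )


def residual_diagnostics_from_arrays(
    resid: np.ndarray, row_t: np.ndarray, row_state: np.ndarray, max_acf_lag: int = 12
) -> ResidualDiagnostics:
    sd = float(np.std(resid))
    degenerate = sd == 0.0 or np.allclose(resid, resid[0])
    if degenerate:
        sd = 0.0
    skew = float(scipy.stats.skew(resid)) if not degenerate else 0.0
    kurt = float(scipy.stats.kurtosis(resid)) if not degenerate else 0.0
    per_period = (
        pd.DataFrame({"t": row_t, "e": resid}).groupby("t")["e"].std(ddof=0)
    )
    acs = {}
    for lag in range(1, max_acf_lag + 1):
        num = den = 0.0
        for s in np.unique(row_state):
            e = resid[row_state == s]
            e = e - e.mean()
            if len(e) > lag and e.std() > 0:
                num += float(e[lag:] @ e[:-lag])
                den += float(e @ e)
        acs[lag] = num / den if den > 0 else np.nan
    return ResidualDiagnostics(
        skewness=skew,
        excess_kurtosis=kurt,
        sd=sd,
        per_period_sd=per_period,
        autocorrelations=pd.Series(acs, name="acf"),
        degenerate=degenerate,
    )


@dataclass
class DistributedLagResults:
    """Estimates from a fitted distributed-lag mortality model."""

    model: DistributedLagModel
    design: DesignInfo
    param_names: list[str]
    params: np.ndarray
    vcov: np.ndarray
    resid: np.ndarray
    nobs: int
    dof_resid: int
    n_params: int
    sigma2: float
    rsquared: float
    rsquared_adj: float
    dropped_controls: list[str]

    # -- coefficient views --------------------------------------------
    @property
    def beta(self) -> pd.Series:
        """Lag coefficients indexed by lag month (leads negative)."""
        return pd.Series(self.params, index=pd.Index(self.design.lag_values, name="lag"))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov)), index=pd.Index(self.design.lag_values, name="lag")
        )

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * scipy.stats.t.sf(np.abs(self.tvalues), self.dof_resid),
            index=self.beta.index,
        )

    def vcov_beta(self) -> pd.DataFrame:
        idx = pd.Index(self.design.lag_values, name="lag")
        return pd.DataFrame(self.vcov, index=idx, columns=idx)

    def resid_series(self) -> pd.Series:
        d = self.design
        idx = pd.MultiIndex.from_arrays(
            [d.states[d.row_state], d.row_t], names=["state", "t"]
        )
        return pd.Series(self.resid, index=idx, name="resid")

    # -- cumulative response ------------------------------------------
    def cumulative(
        self, horizon: int | None = None, conf_level: float = 0.95
    ) -> CumulativeResponse:
        """Cumulative response over the full lead/lag grid, truncated at
        ``horizon`` on the lag side (default: the LagSpec horizon)."""
        lg = self.model.lags
        horizon = lg.cumulative_horizon if horizon is None else horizon
        if horizon > lg.n_lags:
            raise ValueError(f"horizon {horizon} exceeds n_lags {lg.n_lags}")
        return cumulative_response(
            self.design.lag_values, self.params, self.vcov, horizon,
            conf_level=conf_level, dof=self.dof_resid,
        )

    # -- derived summaries --------------------------------------------
    def quadratic_irf(self, lag_range: tuple[int, int] | None = None) -> QuadraticFit:
        lr = lag_range or (0, self.model.lags.cumulative_horizon)
        return QuadraticFit.from_beta(self.beta, lr)

    def diagnostics(self) -> ResidualDiagnostics:
        d = self.design
        return residual_diagnostics_from_arrays(self.resid, d.row_t, d.row_state)

    def wald_leads(self) -> tuple[float, float]:
        """Joint F-test that every lead coefficient is zero (falsification)."""
        sel = self.design.lag_values < 0
        q = int(sel.sum())
        if q == 0:
            raise ValueError("model has no lead terms")
        b = self.params[sel]
        V = self.vcov[np.ix_(sel, sel)]
        stat = float(b @ np.linalg.solve(V, b)) / q
        p = float(scipy.stats.f.sf(stat, q, self.dof_resid))
        return stat, p

    def vcov_clustered(self, by: str = "state") -> pd.DataFrame:
        """Cluster-robust covariance of the exposure block (not the default)."""
        d = self.design
        if by == "state":
            cl = d.row_state
        else:
            key = self.model.panel.df.set_index(["state", "t"])[by]
            cl = pd.factorize(
                [key.loc[(d.states[s], t)] for s, t in zip(d.row_state, d.row_t)]
            )[0]
        Xw = d.exposure if d.weights is None else d.exposure * np.sqrt(d.weights)[:, None]
        Xres = self.model._projector.residualize(Xw)
        k = Xres.shape[1]
        meat = np.zeros((k, k))
        for c in np.unique(cl):
            u = Xres[cl == c].T @ self.resid[cl == c]
            meat += np.outer(u, u)
        G = len(np.unique(cl))
        xtx_inv = self.vcov / self.sigma2
        corr = G / (G - 1) * (self.nobs - 1) / self.dof_resid
        V = corr * xtx_inv @ meat @ xtx_inv
        idx = pd.Index(d.lag_values, name="lag")
        return pd.DataFrame(V, index=idx, columns=idx)

    # -- presentation ---------------------------------------------------
    def summary(self, horizon: int | None = None) -> str:
        from . import reporting

        lg = self.model.lags
        horizon = horizon or lg.cumulative_horizon
        cum = self.cumulative(horizon)
        om, se = cum.at(horizon)
        b0 = float(self.beta.loc[0])
        se0 = float(self.bse.loc[0])
        lines = [
            "Distributed-lag excess mortality model",
            "=" * 54,
            f"observations            {self.nobs}",
            f"states                  {len(self.design.states)}",
            f"estimation months       {self.design.est_months[0]}..{self.design.est_months[-1]}",
            f"leads / lags            {lg.n_leads} / {lg.n_lags}",
            f"parameters (total)      {self.n_params}",
            f"residual dof            {self.dof_resid}",
            f"R2 / adj. R2            {self.rsquared:.4f} / {self.rsquared_adj:.4f}",
            "-" * 54,
            "landfall-month effect   "
            + reporting.format_estimate(b0, b0 / se0 if se0 else np.inf),
            f"cumulative at {horizon:3d} mo    " + reporting.format_estimate(om, om / se if se else np.inf),
            "  (deaths per 100,000 per m/s; +/- is the standard error)",
        ]
        if self.design.lag_values.min() < 0:
            f, p = self.wald_leads()
            lines.append(f"lead falsification      F = {f:.3f}, p = {p:.3f}")
        if self.dropped_controls:
            lines.append(f"dropped collinear controls: {self.dropped_controls}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One row per lag: coefficient, SE, t, p."""
        return pd.DataFrame(
            {"beta": self.beta, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )

    def plot_irf(self, ax=None, lag_range: tuple[int, int] | None = None):
        """Plot beta_l with 95% CI band and the quadratic approximation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b, s = self.beta, self.bse
        q = scipy.stats.t.ppf(0.975, self.dof_resid)
        ax.axhline(0, color="k", lw=0.5)
        ax.plot(b.index, b.values, color="seagreen", lw=1)
        ax.fill_between(b.index, b - q * s, b + q * s, alpha=0.25, color="seagreen")
        try:
            qf = self.quadratic_irf(lag_range)
            xs = np.arange(qf.lag_range[0], qf.lag_range[1] + 1)
            ax.plot(xs, qf(xs), "r--", lw=1)
        except ValueError:
            pass
        ax.set_xlabel("months since landfall")
        ax.set_ylabel("deaths per 100,000 per m/s")
        return ax
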