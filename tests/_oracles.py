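"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (dense dummy matrices, double
loops) and shares no code with the package's solver paths.
"""

from __future__ import annotations

import numpy as np


def dense_design(model):
    """Materialize the full dummy-variable design matrix of a model."""
    d = model.build_design()
    ct = model.controls
    row_state, row_t = d.row_state, d.row_t
    cal = (row_t - 1) % 12
    o_min, o_max = model.panel.observed_t_range
    x = (row_t - o_min) / max(o_max - o_min, 1)
    cols = [d.exposure]
    S = len(d.states)
    if ct.state_month_fe:
        for j in range(S):
            for m in range(12):
                mask = ((row_state == j) & (cal == m)).astype(float)
                cols.append(mask[:, None])
                if ct.state_seasonal_trend:
                    cols.append((mask * x)[:, None])
    elif ct.state_fe:
        for j in range(S):
            cols.append((row_state == j).astype(float)[:, None])
    if ct.month_of_sample_fe:
        for t in d.est_months:
            cols.append((row_t == t).astype(float)[:, None])
    if d.continuous.size:
        cols.append(d.continuous)
    return np.hstack(cols), d.exposure.shape[1], d


def dense_exposure_ols(model):
    """Exposure coefficients, covariance and dof from one dense solve."""
    X, k, d = dense_design(model)
    y = d.y
    if d.weights is not None:
        sw = np.sqrt(d.weights)
        X = X * sw[:, None]
        y = y * sw
    beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    # covariance of the exposure block via dense partialling
    C = X[:, k:]
    coef, *_ = np.linalg.lstsq(C, X[:, :k], rcond=None)
    Xres = X[:, :k] - C @ coef
    rank = np.linalg.matrix_rank(X)
    resid = y - X @ beta_full
    sigma2 = resid @ resid / (len(y) - rank)
    vcov = sigma2 * np.linalg.inv(Xres.T @ Xres)
    return beta_full[:k], vcov, len(y) - rank


def brute_force_burden(events, beta, populations, horizon):
    """Double loop over (event, lag) of population/1e5 * beta_l * z."""
    total = 0.0
    monthly = {}
    t_hi = int(populations.index.max())
    for ev in events.itertuples(index=False):
        for lag in range(horizon + 1):
            t = ev.t + lag
            if t > t_hi or t < populations.index.min():
                continue
            d = populations.loc[t, ev.state] / 1e5 * beta[lag] * ev.incidence
            total += d
            monthly[t] = monthly.get(t, 0.0) + d
    return total, monthly
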