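"""High-dimensional fixed-effect absorption by alternating projections.

The baseline mortality model carries several fixed-effect families that
are far too large to include as explicit dummy columns (state-by-calendar
-month intercepts and linear trends, national month-of-sample effects).
Following the Frisch-Waugh-Lovell theorem, the outcome and the exposure
block are residualized against the span of those families plus any
remaining continuous control columns; OLS on the residualized exposure
then reproduces the exposure coefficients (and their classical
covariance block) of the full dense regression exactly.

Each :class:`AbsorptionGroup` is a partition of the observations together
with a small within-group regressor basis (``[1]`` for a plain fixed
effect, ``[1, x]`` for a group-specific linear trend).  Projection onto
one group's span has a closed form using per-group Gram matrices; the
projection onto the union of several groups is computed by the method of
alternating projections, which converges linearly for intersecting
subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp


class RankError(np.linalg.LinAlgError):
    """Raised when a design is rank deficient beyond the recorded drops."""


class AbsorptionGroup:
    """One fixed-effect family: a partition plus within-group regressors.

    Parameters
    ----------
    codes : int array (n,)
        Group membership, values in ``0..n_groups-1``.
    regressors : array (n, q)
        Within-group regressor columns; the first should be the
        intercept (ones) for a standard fixed effect.  ``q = 2`` with
        ``[1, x]`` absorbs a group-specific linear trend in ``x``.
    """

    def __init__(self, codes: np.ndarray, regressors: np.ndarray, name: str = "") -> None:
        codes = np.asarray(codes)
        if codes.min() < 0:
            raise ValueError("codes must be non-negative")
        self.codes = codes
        self.Z = np.atleast_2d(np.asarray(regressors, dtype=float))
        if self.Z.shape[0] != len(codes):
            self.Z = self.Z.T
        self.q = self.Z.shape[1]
        self.n_groups = int(codes.max()) + 1
        self.name = name or f"fe[{self.n_groups}x{self.q}]"
        n = len(codes)
        self._S = sp.csr_matrix(
            (np.ones(n), (codes, np.arange(n))), shape=(self.n_groups, n)
        )
        # per-group Gram matrices Z_g' Z_g, stacked (G, q, q)
        gram = np.empty((self.n_groups, self.q, self.q))
        for a in range(self.q):
            for b in range(a, self.q):
                gram[:, a, b] = self._S @ (self.Z[:, a] * self.Z[:, b])
                gram[:, b, a] = gram[:, a, b]
        self._gram_inv = self._invert_grams(gram)

    @staticmethod
    def _invert_grams(gram: np.ndarray) -> np.ndarray:
        G, q, _ = gram.shape
        if q == 1:
            inv = np.zeros_like(gram)
            nz = gram[:, 0, 0] > 0
            inv[nz, 0, 0] = 1.0 / gram[nz, 0, 0]
            return inv
        if q == 2:
            a, b, d = gram[:, 0, 0], gram[:, 0, 1], gram[:, 1, 1]
            det = a * d - b * b
            inv = np.zeros_like(gram)
            ok = det > 1e-12 * np.maximum(a * d, 1e-300)
            inv[ok, 0, 0] = d[ok] / det[ok]
            inv[ok, 1, 1] = a[ok] / det[ok]
            inv[ok, 0, 1] = inv[ok, 1, 0] = -b[ok] / det[ok]
            # degenerate groups (e.g. a single x value): keep the intercept only
            deg = ~ok & (a > 0)
            inv[deg, 0, 0] = 1.0 / a[deg]
            return inv
        return np.array([np.linalg.pinv(g) for g in gram])

    def project(self, X: np.ndarray) -> np.ndarray:
        """Fitted values of each column of X on this group's span."""
        X2 = X[:, None] if X.ndim == 1 else X
        sums = np.stack([self._S @ (self.Z[:, k, None] * X2) for k in range(self.q)], axis=1)
        coef = np.einsum("gab,gbc->gac", self._gram_inv, sums)  # (G, q, C)
        fitted = np.zeros_like(X2)
        for k in range(self.q):
            fitted += self.Z[:, k, None] * coef[self.codes, k, :]
        return fitted[:, 0] if X.ndim == 1 else fitted


def residualize_groups(
    groups: list[AbsorptionGroup],
    X: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 2000,
) -> np.ndarray:
    """Residual of X on the union span of the groups (alternating projections)."""
    if not groups:
        return X.copy()
    R = np.array(X, dtype=float, copy=True)
    one_dim = R.ndim == 1
    if one_dim:
        R = R[:, None]
    scale = max(float(np.max(np.abs(R), initial=0.0)), 1.0)
    if len(groups) == 1:
        R -= groups[0].project(R)
        return R[:, 0] if one_dim else R
    for _ in range(max_iter):
        delta = 0.0
        for g in groups:
            F = g.project(R)
            R -= F
            d = float(np.max(np.abs(F), initial=0.0))
            delta = max(delta, d)
        if delta <= tol * scale:
            break
    return R[:, 0] if one_dim else R


@dataclass
class ControlProjector:
    """Annihilator of the full control span (fixed effects + continuous).

    Fit once per panel/specification; ``residualize`` can then be applied
    repeatedly to fresh exposure blocks (as the placebo harness does)
    at the cost of the alternating projections plus one dense matmul.
    """

    groups: list[AbsorptionGroup]
    continuous: np.ndarray | None = None          # (n, C) raw continuous controls
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.dropped: list[str] = []
        self.rank_continuous = 0
        self._Q: np.ndarray | None = None
        C = self.continuous
        if C is not None and C.size:
            Cres = residualize_groups(self.groups, C)
            Q, R, piv = scipy.linalg.qr(Cres, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            if diag.size and diag[0] > 0:
                thresh = max(Cres.shape) * np.finfo(float).eps * diag[0]
                rank = int(np.sum(diag > max(thresh, 1e-9 * diag[0])))
            else:
                rank = 0
            self.rank_continuous = rank
            if self.names is not None:
                self.dropped = [self.names[j] for j in piv[rank:]]
            self._Q = Q[:, :rank]

    def residualize(self, X: np.ndarray) -> np.ndarray:
        """Residual of X on the span of all controls."""
        R = residualize_groups(self.groups, X)
        if self._Q is not None and self._Q.shape[1]:
            R = R - self._Q @ (self._Q.T @ R)
        return R


def fe_union_rank(
    n_state_cells: int,
    cells_per_state: int,
    with_group_trend: bool,
    n_time_cells: int,
    n_regions: int,
) -> int:
    """Rank of the union of the two fixed-effect families.

    The first family partitions observations into ``n_state_cells``
    state-by-calendar-month (or state) cells, each with an intercept and
    optionally a linear trend; the second is one intercept per
    (region, month-of-sample) cell.  Their spans overlap exactly in the
    functions that depend on (region, calendar month) alone -- linear in
    t when the trend basis is present -- because calendar month is a
    deterministic function of month-of-sample.  Valid for generic panels
    with at least two years per cell.
    """
    q = 2 if with_group_trend else 1
    rank = q * n_state_cells
    if n_time_cells:
        overlap = q * cells_per_state * n_regions if n_state_cells else 0
        rank += n_time_cells - overlap
    return rank
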