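"""Rounding and formatting conventions for reported estimates.

Published estimates in this literature are printed as ``estimate (+/- se)``
with the uncertainty at two significant figures, the t-statistic making
the pair self-consistent (se = estimate / t).  These helpers reproduce
that arithmetic so tables regenerated from a fit round identically.
"""

from __future__ import annotations

import math


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def se_from_t(estimate: float, t: float, sig: int = 2) -> float:
    """Standard error implied by a printed estimate and t-statistic."""
    if t == 0:
        raise ZeroDivisionError("t-statistic is zero")
    return round_sig(estimate / t, sig)


def per_event_total(per_ms: float, incidence_ms: float, decimals: int = 2) -> float:
    """Scale a per-m/s cumulative response by an event's incidence.

    E.g. cumulative deaths per 100,000 per m/s times the average
    state-level event incidence in m/s gives per-event deaths per
    100,000, rounded at reporting precision.
    """
    return round(per_ms * incidence_ms, decimals)


def format_estimate(estimate: float, t: float, decimals: int = 3) -> str:
    """``estimate (+/- se)`` with the se derived as estimate / t."""
    se = se_from_t(estimate, t) if t not in (0.0, float("inf")) else 0.0
    return f"{estimate:.{decimals}f} (+/- {se:g})"
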