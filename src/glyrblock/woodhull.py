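"""Woodhull analysis: fractional electrical distance from IC50(V).

The Woodhull relation IC50(V) = IC50(0) exp(-delta F V / RT) log-linearizes
to ln IC50 = ln IC50(0) - (delta F / RT) V, so delta is estimated by ordinary
least squares of ln IC50 on membrane potential: delta = -slope * RT/F.  The
default workflow fits each cell's voltage series separately and then
aggregates delta as mean +/- SEM across cells (the layout of the
per-subtype summary tables); a pooled fit over all cells is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, rt_f_mV

__all__ = ["WoodhullFit", "fit_woodhull", "two_point_delta", "aggregate_delta"]


@dataclass(frozen=True)
class WoodhullFit:
    """Estimated fractional electrical distance and zero-voltage IC50."""

    delta: float
    ic50_0_uM: float
    se_delta: float
    se_log_ic50_0: float
    T: float
    n_points: int
    pooled: bool = False


def fit_woodhull(ic50_by_voltage, T: float = DEFAULT_TEMPERATURE,
                 pooled: bool = False) -> WoodhullFit:
    """OLS of ln IC50 on V; delta = -slope * RT/F, IC50(0) = exp(intercept).

    ``ic50_by_voltage`` is a sequence of (V mV, IC50 uM) pairs with at least
    two distinct voltages and positive IC50 values.
    """
    pairs = [(float(v), float(ic)) for v, ic in ic50_by_voltage]
    if len(pairs) < 2 or len({v for v, _ in pairs}) < 2:
        raise ValueError("need IC50 values at >= 2 distinct voltages")
    v = np.array([p[0] for p in pairs])
    ic = np.array([p[1] for p in pairs])
    if np.any(ic <= 0) or np.any(~np.isfinite(ic)):
        raise ValueError("IC50 values must be positive and finite")
    rtf = rt_f_mV(T)
    if len(pairs) == 2:
        # exact two-point solution (linregress SEs undefined at n=2)
        slope = (np.log(ic[1]) - np.log(ic[0])) / (v[1] - v[0])
        intercept = np.log(ic[0]) - slope * v[0]
        se_slope = np.nan
        se_intercept = np.nan
    else:
        res = stats.linregress(v, np.log(ic))
        slope, intercept = res.slope, res.intercept
        se_slope, se_intercept = res.stderr, res.intercept_stderr
    return WoodhullFit(delta=float(-slope * rtf),
                       ic50_0_uM=float(np.exp(intercept)),
                       se_delta=float(se_slope * rtf) if np.isfinite(se_slope) else np.nan,
                       se_log_ic50_0=float(se_intercept) if np.isfinite(se_intercept) else np.nan,
                       T=T, n_points=len(pairs), pooled=pooled)


def two_point_delta(ic50_a: float, v_a: float, ic50_b: float, v_b: float,
                    T: float = DEFAULT_TEMPERATURE) -> float:
    """Closed-form delta from two (IC50, V) points:
    (RT/F) ln(IC50_a/IC50_b) / (V_b - V_a)."""
    if v_a == v_b:
        raise ValueError("voltages must differ")
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50 values must be positive")
    return rt_f_mV(T) * np.log(ic50_a / ic50_b) / (v_b - v_a)


def aggregate_delta(per_cell_deltas) -> dict:
    """Mean +/- SEM of per-cell delta estimates; SEM is None for n = 1."""
    deltas = [float(d) for d in np.atleast_1d(per_cell_deltas)]
    if len(deltas) == 0:
        raise ValueError("no per-cell fits to aggregate")
    arr = np.array(deltas)
    n = len(arr)
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return {"mean": float(arr.mean()), "sem": sem, "n": n}
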