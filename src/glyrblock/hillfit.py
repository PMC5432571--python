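"""Hill equation fits and block-stoichiometry inference.

Two forms are fitted by nonlinear least squares:

    inhibition:  f(c) = Imax / (1 + (c / IC50)^nH)      (Imax fixed to 1
                 by default, fraction-remaining data are normalized)
    activation:  I(a) = Imax / (1 + (EC50 / a)^nH)      (Imax free)

IC50/EC50 are fitted in log space with nH bounded to [0.2, 4]; a small
multi-start over nH guards against sparse-grid local minima.  Per-voltage
fits assembled over a dose-inhibition table give the IC50(V)/nH(V) input for
the Woodhull analysis, and the mean Hill coefficient gives the 1- vs 2-site
heuristic (nH > 1.3 suggests two blocking molecules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "fit_hill_inhibition",
    "fit_hill_activation",
    "ic50_voltage_table",
    "infer_stoichiometry",
]

NH_BOUNDS = (0.2, 4.0)
NH_STARTS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class HillFit:
    """Fitted half-effect concentration (uM), Hill coefficient, maximum,
    standard errors, residual norm and convergence flag."""

    ic50: float
    nh: float
    imax: float
    se_ic50: float
    se_nh: float
    se_imax: float
    resid_norm: float
    converged: bool


def _hill_inhibition(c, log_ic50, nh, imax):
    return imax / (1.0 + (c / np.exp(log_ic50)) ** nh)


def _hill_activation(a, log_ec50, nh, imax):
    return imax / (1.0 + (np.exp(log_ec50) / a) ** nh)


def _fit(model, x, y, fix_imax, weights):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    # crude IC50 guess: concentration nearest half-effect
    ymax = 1.0 if fix_imax else max(y.max(), 1e-12)
    guess_idx = int(np.argmin(np.abs(y - 0.5 * ymax)))
    log_c0 = np.log(x[guess_idx])
    best = None
    for nh0 in NH_STARTS:
        if fix_imax:
            p0 = [log_c0, nh0]
            f = lambda c, lc, nh: model(c, lc, nh, 1.0)
            bounds = ([np.log(x.min()) - 7, NH_BOUNDS[0]],
                      [np.log(x.max()) + 7, NH_BOUNDS[1]])
        else:
            p0 = [log_c0, nh0, ymax]
            f = model
            bounds = ([np.log(x.min()) - 7, NH_BOUNDS[0], 1e-9],
                      [np.log(x.max()) + 7, NH_BOUNDS[1], 10 * ymax + 1e-9])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(f, x, y, p0=p0, sigma=sigma, bounds=bounds,
                                       maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(f(x, *popt) - y))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                       np.inf, converged=False)
    popt, pcov, resid = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ic50 = float(np.exp(popt[0]))
    se_ic50 = ic50 * float(se[0])  # delta method from log-space SE
    imax = float(popt[2]) if not fix_imax else 1.0
    se_imax = float(se[2]) if not fix_imax else 0.0
    return HillFit(ic50=ic50, nh=float(popt[1]), imax=imax,
                   se_ic50=se_ic50, se_nh=float(se[1]), se_imax=se_imax,
                   resid_norm=resid, converged=True)


def fit_hill_inhibition(concs_uM, fractions, weights=None,
                        fix_imax: bool = True) -> HillFit:
    """Fit f = Imax/(1+(c/IC50)^nH) to fraction-remaining data."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(~np.isfinite(fractions)) or np.any(fractions < -0.2) or np.any(fractions > 1.2):
        raise ValueError("fractions must be finite and lie in [0, 1.2] (noise allowance)")
    return _fit(_hill_inhibition, concs_uM, fractions, fix_imax, weights)


def fit_hill_activation(concs_uM, responses, weights=None) -> HillFit:
    """Fit I = Imax/(1+(EC50/a)^nH) with free Imax to dose-response data."""
    return _fit(_hill_activation, concs_uM, responses, fix_imax=False,
                weights=weights)


def ic50_voltage_table(table: pd.DataFrame, vgrid=None,
                       per_cell: bool = True, min_concs: int = 3) -> pd.DataFrame:
    """Per-voltage Hill inhibition fits from a tidy dose-inhibition table.

    ``table`` needs columns cell, voltage_mV, nfa_uM, fraction.  Returns one
    row per (cell, V) — plus pooled rows fitted across cells (cell='pooled')
    — with IC50, nH and their SEs.  Voltages with fewer than ``min_concs``
    concentrations are skipped with a warning.
    """
    required = {"cell", "voltage_mV", "nfa_uM", "fraction"}
    if table is None or len(table) == 0:
        raise ValueError("empty dose-inhibition table")
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if vgrid is None:
        vgrid = sorted(table["voltage_mV"].unique())
    rows = []
    groups = ([(c, g) for c, g in table.groupby("cell")] if per_cell else []) \
        + [("pooled", table)]
    for cell, g in groups:
        for v in vgrid:
            gv = g[np.isclose(g["voltage_mV"], v)]
            if gv["nfa_uM"].nunique() < min_concs:
                warnings.warn(f"voltage {v} mV skipped for {cell}: "
                              f"fewer than {min_concs} concentrations")
                continue
            fit = fit_hill_inhibition(gv["nfa_uM"].to_numpy(),
                                      np.clip(gv["fraction"].to_numpy(), -0.2, 1.2))
            rows.append({"cell": cell, "voltage_mV": v, "ic50_uM": fit.ic50,
                         "se_ic50_uM": fit.se_ic50, "nh": fit.nh,
                         "se_nh": fit.se_nh, "converged": fit.converged})
    return pd.DataFrame(rows)


def infer_stoichiometry(nh_values, threshold: float = 1.3) -> dict:
    """Heuristic 1- vs 2-site call from per-voltage Hill coefficients.

    mean nH strictly above ``threshold`` suggests two blocking molecules;
    at or below, one.  This is an interpretive rule of thumb, not a model
    comparison.
    """
    nh = np.asarray([x for x in np.atleast_1d(nh_values) if np.isfinite(x)], dtype=float)
    if len(nh) == 0:
        return {"n_sites": None, "mean_nh": np.nan,
                "rationale": "undetermined: no converged Hill fits"}
    mean_nh = float(nh.mean())
    n_sites = 2 if mean_nh > threshold else 1
    return {"n_sites": n_sites, "mean_nh": mean_nh, "threshold": threshold,
            "rationale": (f"mean nH {mean_nh:.2f} "
                          + (">" if n_sites == 2 else "<=") + f" {threshold} "
                          f"suggests {'two blocking molecules' if n_sites == 2 else 'a single blocking molecule'}"
                          " (heuristic)")}
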