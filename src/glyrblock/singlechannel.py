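"""Single-channel idealization, flicker-burst analysis and block rates.

An open-channel blocker turns long rectangular openings into bursts of
openings interrupted by brief blocked sojourns ("flicker").  At a fixed
potential the blocked dwell is exponential with mean 1/koff, and the rate of
flicker gaps per unit open time is kon*[blocker], so both rate constants are
readable from an idealized event list:

    koff = 1 / mean(flicker gap duration)
    kon  = (number of flicker gaps / total open time) / [blocker]

Idealization is plain half-amplitude threshold crossing with a two-sample
minimum event width; shut-time distributions are fitted as exponential
mixtures by EM, and the burst criterion t_crit defaults to the
equal-misclassification intersection of the two fitted shut components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .synth import CurrentTrace

__all__ = [
    "IdealizedEvents",
    "ExponentialMixture",
    "BurstTable",
    "idealize",
    "fit_dwell_exponentials",
    "t_crit_from_mixture",
    "detect_bursts",
    "estimate_block_rates",
]


@dataclass
class IdealizedEvents:
    """Alternating (level, duration s, amplitude pA) records."""

    levels: list[str]           # 'open' | 'shut'
    durations: np.ndarray       # s
    amplitudes: np.ndarray      # pA (mean within event)

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("event durations must be positive")
        for a, b in zip(self.levels, self.levels[1:]):
            if a == b:
                raise ValueError("events must alternate open/shut")

    def dwells(self, level: str) -> np.ndarray:
        return self.durations[[i for i, lv in enumerate(self.levels) if lv == level]]

    def __len__(self):
        return len(self.levels)


def idealize(trace: CurrentTrace, baseline_pA: float, open_amplitude_pA: float,
             min_samples: int = 2) -> IdealizedEvents:
    """Half-amplitude threshold idealization.

    Samples are classified against the midpoint between baseline and open
    level; runs shorter than ``min_samples`` are merged into their
    neighbours.  Requires the two levels to be separated by more than 3x the
    recording noise SD.
    """
    i = trace.current_pA
    sep = abs(open_amplitude_pA - baseline_pA)
    noise_sd = trace.meta.get("noise_sd", float(np.std(i[:50])) if len(i) >= 50 else 0.0)
    if noise_sd and sep <= 3.0 * noise_sd:
        raise ValueError(f"levels inseparable: |open-baseline|={sep:.2f} pA "
                         f"<= 3*noise_sd={3*noise_sd:.2f} pA")
    thresh = 0.5 * (baseline_pA + open_amplitude_pA)
    if open_amplitude_pA >= baseline_pA:
        is_open = i >= thresh
    else:
        is_open = i <= thresh
    if not is_open.any():
        return IdealizedEvents(levels=[], durations=np.array([]), amplitudes=np.array([]))

    # run-length encode, then merge short runs into the preceding neighbour
    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(i)]])
    runs = [(bool(is_open[s]), s, e) for s, e in zip(starts, ends)]
    merged: list[list] = []
    for lv, s, e in runs:
        if merged and (e - s < min_samples or merged[-1][0] == lv):
            merged[-1][2] = e
        else:
            merged.append([lv, s, e])
    # a leading short run joins forward
    if len(merged) >= 2 and merged[0][2] - merged[0][1] < min_samples:
        merged[1][1] = merged[0][1]
        merged.pop(0)
    # merging may have re-created equal neighbours
    out: list[list] = []
    for lv, s, e in merged:
        if out and out[-1][0] == lv:
            out[-1][2] = e
        else:
            out.append([lv, s, e])
    dt = 1.0 / trace.meta.get("sample_rate", 1.0 / (trace.time_s[1] - trace.time_s[0]))
    levels = ["open" if lv else "shut" for lv, _, _ in out]
    durations = np.array([(e - s) * dt for _, s, e in out])
    amplitudes = np.array([float(i[s:e].mean()) for _, s, e in out])
    return IdealizedEvents(levels=levels, durations=durations, amplitudes=amplitudes)


@dataclass(frozen=True)
class ExponentialMixture:
    """Rates (s^-1), weights and log-likelihood of an exponential mixture."""

    rates: tuple
    weights: tuple
    loglik: float
    converged: bool

    @property
    def taus(self) -> tuple:
        return tuple(1.0 / r for r in self.rates)


def fit_dwell_exponentials(durations, n_components: int = 1,
                           max_iter: int = 500, tol: float = 1e-10) -> ExponentialMixture:
    """Maximum-likelihood exponential(-mixture) fit to dwell times.

    One component has the closed form rate = 1/mean; two components are
    fitted by EM initialized from the short/long split of the data.
    Requires >= 50 dwells for one component and >= 200 for two.
    """
    x = np.asarray(durations, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    need = 50 if n_components == 1 else 200
    if len(x) < need:
        raise ValueError(f"need >= {need} dwells for {n_components} component(s), got {len(x)}")
    if np.any(x <= 0):
        raise ValueError("dwell durations must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all dwell durations equal")
    if n_components == 1:
        rate = 1.0 / x.mean()
        ll = float(np.sum(np.log(rate) - rate * x))
        return ExponentialMixture(rates=(rate,), weights=(1.0,), loglik=ll, converged=True)

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    rates = np.array([1.0 / max(lo.mean(), 1e-12), 1.0 / hi.mean()])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = np.log(w)[:, None] + np.log(rates)[:, None] - rates[:, None] * x[None, :]
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        resp = np.exp(log_comp - log_norm)
        ll = float(log_norm.sum())
        w = resp.mean(axis=1)
        rates = resp.sum(axis=1) / (resp @ x)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    order = np.argsort(rates)[::-1]  # fast component first
    return ExponentialMixture(rates=tuple(float(r) for r in rates[order]),
                              weights=tuple(float(v) for v in w[order]),
                              loglik=ll, converged=converged)


def t_crit_from_mixture(mix: ExponentialMixture) -> float:
    """Equal-misclassification burst criterion between two shut components.

    Solves w_fast * exp(-r_fast t) = w_slow * (1 - exp(-r_slow t)) ... the
    standard criterion equating the number of misclassified short and long
    gaps; falls back to the geometric mean of the two time constants when
    the equation has no bracketable root.
    """
    if len(mix.rates) != 2:
        raise ValueError("t_crit needs a two-component shut-time mixture")
    (rf, rs), (wf, ws) = mix.rates, mix.weights

    def mis(t):
        return wf * np.exp(-rf * t) - ws * (1.0 - np.exp(-rs * t))

    lo, hi = 1.0 / rf, 1.0 / rs
    try:
        return float(brentq(mis, lo * 1e-3, hi * 1e3))
    except ValueError:
        return float(np.sqrt(lo * hi))


@dataclass
class BurstTable:
    """Bursts delimited by shut periods >= t_crit."""

    bursts: pd.DataFrame        # start_s, end_s, n_openings, n_flicker_gaps, mean_gap_s
    t_crit: float
    total_open_time_s: float
    flicker_gap_durations: np.ndarray = field(default_factory=lambda: np.array([]))


def detect_bursts(events: IdealizedEvents, t_crit: float) -> BurstTable:
    """Group openings into bursts: shut periods < t_crit are intra-burst
    flicker gaps, longer ones terminate the burst."""
    if len(events) == 0:
        return BurstTable(bursts=pd.DataFrame(columns=["start_s", "end_s", "n_openings",
                                                       "n_flicker_gaps", "mean_gap_s"]),
                          t_crit=t_crit, total_open_time_s=0.0)
    t = 0.0
    rows = []
    cur = None
    gaps_all = []
    open_time = 0.0
    for lv, dur in zip(events.levels, events.durations):
        if lv == "open":
            open_time += dur
            if cur is None:
                cur = {"start_s": t, "end_s": t + dur, "n_openings": 1,
                       "gaps": []}
            else:
                cur["n_openings"] += 1
                cur["end_s"] = t + dur
        else:
            if cur is not None:
                if dur < t_crit:
                    cur["gaps"].append(dur)
                else:
                    rows.append(cur)
                    cur = None
        t += dur
    if cur is not None:
        rows.append(cur)
    for r in rows:
        gaps_all.extend(r["gaps"])
        r["n_flicker_gaps"] = len(r["gaps"])
        r["mean_gap_s"] = float(np.mean(r["gaps"])) if r["gaps"] else np.nan
        del r["gaps"]
    return BurstTable(bursts=pd.DataFrame(rows), t_crit=t_crit,
                      total_open_time_s=open_time,
                      flicker_gap_durations=np.array(gaps_all))


def estimate_block_rates(bursts: BurstTable, blocker_uM: float,
                         min_gaps: int = 30) -> tuple[float, float]:
    """(kon uM^-1 s^-1, koff s^-1) from flicker gaps within bursts.

    Flicker gaps are blocked sojourns truncated at t_crit, so the plain
    reciprocal mean overestimates koff when 1/koff is not << t_crit.  koff
    is therefore the truncated-exponential MLE (solves
    mean_obs = 1/k - t_crit/(e^(k t_crit) - 1)) and the observed gap rate
    is corrected for the censored fraction 1 - e^(-koff t_crit) before
    dividing by the concentration to get kon.
    """
    if blocker_uM <= 0:
        raise ValueError("no blocker present: blocker concentration must be positive")
    gaps = bursts.flicker_gap_durations
    if len(gaps) < min_gaps:
        raise ValueError(f"need >= {min_gaps} flicker gaps, got {len(gaps)}")
    if bursts.total_open_time_s <= 0:
        raise ValueError("no open time recorded")
    mean_obs = float(gaps.mean())
    tc = float(bursts.t_crit)

    def resid(k):
        kt = min(k * tc, 700.0)
        return 1.0 / k - tc / np.expm1(kt) - mean_obs

    # truncation shrinks the observed mean, so the true rate lies below the
    # naive 1/mean; the mean of an exponential censored at tc is < tc/2 only
    # when estimation is possible at all
    k_naive = 1.0 / mean_obs
    lo = 1e-3 * k_naive
    if np.isfinite(tc) and tc > 0 and mean_obs < 0.5 * tc and resid(lo) > 0:
        koff = float(brentq(resid, lo, k_naive))
    else:
        koff = k_naive
    observed_fraction = -np.expm1(-koff * tc) if np.isfinite(tc) else 1.0
    gap_rate = len(gaps) / bursts.total_open_time_s / max(observed_fraction, 1e-12)
    kon = gap_rate / blocker_uM
    return float(kon), float(koff)
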