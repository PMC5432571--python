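"""Extract measured quantities from current traces.

Covers the four readouts of the experimental analysis: percent inhibition
from long-protocol sweeps (maximal-block amplitude I1 against the post-wash
quasi-stationary amplitude I2), fraction-remaining-vs-voltage from ramp
pairs, a rectification index, and the cell quality filter (input resistance
>= 150 MOhm, run-down <= 30%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import CurrentTrace

__all__ = [
    "InhibitionMeasurement",
    "FractionRemainingCurve",
    "measure_inhibition_long",
    "ramp_fraction_remaining",
    "average_fraction_curves",
    "rectification_index",
    "quality_filter",
]


@dataclass(frozen=True)
class InhibitionMeasurement:
    """I1 (current at maximal inhibition), I2 (post-wash reference) and
    the derived percent inhibition 100*(1 - I1/I2)."""

    i1_pA: float
    i2_pA: float

    @property
    def percent_inhibition(self) -> float:
        return 100.0 * (1.0 - self.i1_pA / self.i2_pA)


@dataclass
class FractionRemainingCurve:
    """f(V) = I_drug/I_control on a fixed voltage grid; masked points are
    dropped (grid voltages where the control current is within the noise)."""

    voltage_mV: np.ndarray
    fraction: np.ndarray
    nfa_uM: float
    excluded_mV: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voltage_mV": self.voltage_mV,
                             "fraction": self.fraction,
                             "nfa_uM": self.nfa_uM})


def measure_inhibition_long(trace: CurrentTrace,
                            window_frac: float = 0.1,
                            wash_frac: float = 0.4,
                            noise_floor_pA: float | None = None) -> InhibitionMeasurement:
    """Percent inhibition from a long-protocol sweep.

    I1 is the mean over the final ``window_frac`` of the co-application
    window; I2 the mean over the final ``wash_frac`` of the post-wash window
    (the quasi-stationary level, robust to desensitization).
    """
    windows = trace.meta.get("solution_windows")
    if windows is None or len(windows) != 3:
        raise ValueError("trace does not follow a three-window long protocol")
    edges = np.concatenate([[0.0], np.cumsum([w[0] for w in windows])])
    t = trace.time_s
    i = trace.current_pA
    co_lo = edges[2] - window_frac * (edges[2] - edges[1])
    m1 = (t >= co_lo) & (t < edges[2])
    wash_lo = edges[3] - wash_frac * (edges[3] - edges[2])
    m2 = (t >= wash_lo) & (t < edges[3])
    i1 = float(i[m1].mean())
    i2 = float(i[m2].mean())
    if noise_floor_pA is None:
        noise_floor_pA = 5.0 * trace.meta.get("noise_sd", 0.0)
    if abs(i2) <= max(noise_floor_pA, 1e-12):
        raise ValueError("no reference current: post-wash amplitude below noise floor")
    return InhibitionMeasurement(i1_pA=i1, i2_pA=i2)


def ramp_fraction_remaining(control: CurrentTrace, drug: CurrentTrace,
                            min_abs_current_pA: float | None = None,
                            vgrid=None, window_mV: float = 3.0) -> FractionRemainingCurve:
    """f(V) = I_drug(V)/I_control(V) on a voltage grid from one ramp pair.

    Each grid point averages all samples (holds included) within
    ``window_mV`` of the grid voltage; the ratio of window means is used.
    Grid voltages where |I_control| falls below ``min_abs_current_pA``
    (default 5x the additive noise SD plus 2% of the largest control
    current, covering multiplicative noise) are masked.
    """
    if control.meta.get("voltage_segments") != drug.meta.get("voltage_segments"):
        raise ValueError("control and drug sweeps follow different voltage protocols")
    if len(control.time_s) != len(drug.time_s):
        raise ValueError("control and drug sweeps are on different time bases")
    v = control.voltage_mV
    if vgrid is None:
        from .synth import DEFAULT_VOLTAGE_GRID
        vgrid = DEFAULT_VOLTAGE_GRID
    vgrid = np.asarray(vgrid, dtype=float)
    if min_abs_current_pA is None:
        min_abs_current_pA = (5.0 * control.meta.get("noise_sd", 0.0)
                              + 0.02 * np.abs(control.current_pA).max())
    volts, fracs, excluded = [], [], []
    for vg in vgrid:
        m = np.abs(v - vg) <= window_mV
        if not m.any():
            excluded.append(vg)
            continue
        ic = control.current_pA[m].mean()
        if abs(ic) < min_abs_current_pA:
            excluded.append(vg)
            continue
        volts.append(vg)
        fracs.append(drug.current_pA[m].mean() / ic)
    conc = drug.meta.get("nfa_uM", np.nan)
    return FractionRemainingCurve(voltage_mV=np.array(volts), fraction=np.array(fracs),
                                  nfa_uM=conc, excluded_mV=np.array(excluded))


def average_fraction_curves(curves: list[FractionRemainingCurve]) -> FractionRemainingCurve:
    """Average f(V) over sweeps (e.g. up- and down-ramps) on the common grid."""
    if not curves:
        raise ValueError("no curves to average")
    common = curves[0].voltage_mV
    for c in curves[1:]:
        common = np.intersect1d(common, c.voltage_mV)
    fr = np.mean([[c.fraction[np.where(c.voltage_mV == vg)[0][0]] for vg in common]
                  for c in curves], axis=0)
    return FractionRemainingCurve(voltage_mV=common, fraction=fr,
                                  nfa_uM=curves[0].nfa_uM,
                                  excluded_mV=np.array([]))


def rectification_index(control: CurrentTrace, v_pos: float = 80.0,
                        v_neg: float = -80.0, window_mV: float = 3.0) -> float:
    """|I(+80)| / |I(-80)| from a ramp sweep; > 1 flags outward rectification."""
    v = control.voltage_mV
    i = control.current_pA
    mp = np.abs(v - v_pos) <= window_mV
    mn = np.abs(v - v_neg) <= window_mV
    if not mp.any() or not mn.any():
        raise ValueError("ramp does not reach both endpoint voltages")
    denom = abs(i[mn].mean())
    if denom == 0:
        raise ValueError("zero current at the negative endpoint")
    return abs(i[mp].mean()) / denom


def quality_filter(cell_meta: dict, min_rin_mohm: float = 150.0,
                   max_run_down: float = 0.30) -> tuple[bool, list[str]]:
    """Exclusion rule: drop cells with Rin < 150 MOhm or run-down > 30%.

    Returns (keep, reasons); missing fields drop the cell with reason
    'unmeasured'.
    """
    reasons = []
    rin = cell_meta.get("rin_mohm")
    rd = cell_meta.get("run_down")
    if rin is None or rd is None:
        return False, ["unmeasured"]
    if rin < min_rin_mohm:
        reasons.append(f"low_input_resistance({rin:.0f}<{min_rin_mohm:.0f}MOhm)")
    if rd > max_run_down:
        reasons.append(f"run_down({100*rd:.0f}%>{100*max_run_down:.0f}%)")
    return (len(reasons) == 0), reasons
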