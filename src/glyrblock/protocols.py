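"""Voltage and solution application protocols.

Two protocols from the experimental design are provided ready-made: the
"ramp" (500 ms hold, 1 s linear sweep between -80 and +80 mV, 500 ms hold)
used to read out the voltage dependence of block in a single sweep, and the
"long" application (glycine 2 s / glycine+NFA 10 s / glycine 5 s at fixed
holding potential) used for percent-inhibition measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "VoltageProtocol",
    "SolutionProtocol",
    "make_ramp_protocol",
    "make_long_protocol",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered contiguous segments (duration s, V_start mV, V_end mV)."""

    segments: tuple[tuple[float, float, float], ...]
    sample_rate: float = 2000.0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, *_ in self.segments:
            if not dur > 0:
                raise ValueError("segment durations must be positive")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _, _ in self.segments))

    def times(self) -> np.ndarray:
        """Sample clock (left-closed, excludes the final endpoint)."""
        n = int(round(self.total_duration * self.sample_rate))
        return np.arange(n) / self.sample_rate

    def voltage(self, t) -> np.ndarray:
        """Piecewise-linear V(t) in mV for scalar or array times."""
        t = np.asarray(t, dtype=float)
        v = np.empty_like(t)
        t0 = 0.0
        for dur, v0, v1 in self.segments:
            m = (t >= t0 - 1e-12) & (t < t0 + dur)
            v[m] = v0 + (v1 - v0) * (t[m] - t0) / dur
            t0 += dur
        v[t >= t0 - 1e-12] = self.segments[-1][2]
        return v


@dataclass(frozen=True)
class SolutionProtocol:
    """Ordered windows (duration s, [glycine] uM, [NFA] uM)."""

    windows: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.windows:
            raise ValueError("protocol needs at least one window")
        for dur, gly, nfa in self.windows:
            if not dur > 0:
                raise ValueError("window durations must be positive")
            if gly < 0 or nfa < 0:
                raise ValueError("concentrations must be non-negative")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _, _ in self.windows))

    def concentrations(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant ([glycine], [NFA]) at times ``t``."""
        t = np.asarray(t, dtype=float)
        gly = np.empty_like(t)
        nfa = np.empty_like(t)
        t0 = 0.0
        for dur, g, n in self.windows:
            m = (t >= t0 - 1e-12) & (t < t0 + dur)
            gly[m], nfa[m] = g, n
            t0 += dur
        tail = t >= t0 - 1e-12
        gly[tail], nfa[tail] = self.windows[-1][1], self.windows[-1][2]
        return gly, nfa

    def window_bounds(self) -> list[tuple[float, float]]:
        edges = np.concatenate([[0.0], np.cumsum([d for d, _, _ in self.windows])])
        return list(zip(edges[:-1], edges[1:]))


def make_ramp_protocol(direction: Literal["up", "down"] = "up",
                       sample_rate: float = 2000.0,
                       v_low: float = -80.0, v_high: float = 80.0,
                       hold_s: float = 0.5, ramp_s: float = 1.0) -> VoltageProtocol:
    """Hold / 1-s linear sweep / hold; 'up' runs v_low -> v_high."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    a, b = (v_low, v_high) if direction == "up" else (v_high, v_low)
    return VoltageProtocol(
        segments=((hold_s, a, a), (ramp_s, a, b), (hold_s, b, b)),
        sample_rate=sample_rate,
    )


def make_long_protocol(glycine_uM: float, nfa_uM: float,
                       durations: tuple[float, float, float] = (2.0, 10.0, 5.0)
                       ) -> SolutionProtocol:
    """Agonist alone / agonist+blocker / agonist alone, default 2/10/5 s."""
    if glycine_uM < 0 or nfa_uM < 0:
        raise ValueError("concentrations must be non-negative")
    d1, d2, d3 = durations
    return SolutionProtocol(windows=(
        (d1, glycine_uM, 0.0),
        (d2, glycine_uM, nfa_uM),
        (d3, glycine_uM, 0.0),
    ))
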