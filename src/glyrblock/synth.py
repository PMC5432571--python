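"""Synthetic whole-cell and single-channel recordings with known ground truth.

The generator integrates the gating/block master equation along the voltage
and solution protocols and renders currents as

    I(t) = N * i(-30mV) * (V - E_rev)/(-30 - E_rev) * rect(V) * sum_i g_i p_i(t)

plus recording noise, i.e. a linear unitary conductance anchored to the mean
single-channel amplitude at -30 mV, a Boltzmann rectification factor, and the
conducting occupancy of the kinetic scheme.  Cell-to-cell amplitude scatter is
lognormal; input resistance and run-down metadata are drawn per cell so the
quality filter has something to act on.

Integration is exact per sample: over each sample interval the generator
matrix is frozen at the midpoint voltage and propagated by eigendecomposition,
so stiff block kinetics cost nothing extra and long fixed-voltage segments
are propagated in a single step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .kinetics import KineticScheme, equilibrium_occupancy
from .constants import rt_f_mV
from .protocols import VoltageProtocol, SolutionProtocol, make_ramp_protocol, make_long_protocol

__all__ = [
    "RecordingConfig",
    "CurrentTrace",
    "CellRecording",
    "SyntheticCohort",
    "simulate_whole_cell",
    "simulate_single_channel",
    "generate_cohort",
]


@dataclass(frozen=True)
class RecordingConfig:
    """Recording and cohort parameters.

    ``unitary_current_at_minus30`` anchors the single-channel amplitude
    (2.8 pA, the mean single-channel amplitude at -30 mV); ``noise_sd`` is
    additive Gaussian noise in pA and ``noise_cv`` multiplicative amplitude
    noise (fraction).  ``imax_cell_cv`` is the lognormal coefficient of
    variation of whole-cell amplitude across cells.
    """

    unitary_current_at_minus30: float = 2.8
    n_channels: int = 200
    e_rev: float = 0.0
    noise_sd: float = 2.0
    noise_cv: float = 0.0
    run_down_per_sweep: float = 0.002
    imax_cell_cv: float = 0.3
    rin_mean_mohm: float = 350.0
    rin_sd_mohm: float = 70.0
    sample_rate: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class CurrentTrace:
    """Sampled current with its voltage protocol and solution metadata."""

    time_s: np.ndarray
    current_pA: np.ndarray
    voltage_mV: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if not (len(self.time_s) == len(self.current_pA) == len(self.voltage_mV)):
            raise ValueError("trace columns must have equal length")


def _transition_arrays(scheme: KineticScheme):
    frm = np.array([scheme.index(t.frm) for t in scheme.transitions])
    to = np.array([scheme.index(t.to) for t in scheme.transitions])
    base = np.array([t.base for t in scheme.transitions])
    lig = np.array([{None: 0, "blocker": 1, "agonist": 2}[t.ligand]
                    for t in scheme.transitions])
    wood = np.array([t.wood_coef for t in scheme.transitions])
    return frm, to, base, lig, wood


def _rate_matrix_fast(scheme, arrays, v_mV, gly, nfa):
    frm, to, base, lig, wood = arrays
    rates = base * np.exp(wood * (v_mV / rt_f_mV(scheme.T)))
    rates = np.where(lig == 1, rates * nfa, rates)
    rates = np.where(lig == 2, rates * scheme.gating.h(gly), rates)
    n = scheme.n_states
    Q = np.zeros((n, n))
    Q[frm, to] = rates
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


def _propagate_constant(Q: np.ndarray, p0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """p(t) for constant generator Q at offsets ``dts`` from p0 (exact)."""
    lam, V = np.linalg.eig(Q.T)
    c = np.linalg.solve(V, p0)
    # (n_t, n_states)
    out = np.real((V[None, :, :] * (c[None, None, :] * np.exp(np.outer(dts, lam))[:, None, :])).sum(axis=2))
    return np.clip(out, 0.0, None)


def occupancy_along(scheme: KineticScheme, vprot: VoltageProtocol,
                    sprot: SolutionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the master equation along the joint protocol.

    Returns the sample clock and state probabilities (n_t, n_states).  The
    initial condition is the equilibrium at the first sample's conditions.
    """
    if abs(vprot.total_duration - sprot.total_duration) > 1e-9:
        raise ValueError("voltage and solution protocols must cover the same duration")
    t = vprot.times()
    v = vprot.voltage(t)
    gly, nfa = sprot.concentrations(t)
    arrays = _transition_arrays(scheme)
    n_t = len(t)
    dt = 1.0 / vprot.sample_rate
    p = np.empty((n_t, scheme.n_states))
    p0 = np.array(list(equilibrium_occupancy(scheme, v[0], gly[0], nfa[0]).values()))
    p[0] = p0

    # segment boundaries where V is constant and solution unchanged allow a
    # single exact propagation; elsewhere (ramps) step sample-by-sample with
    # the generator frozen at the midpoint voltage
    i = 0
    while i < n_t - 1:
        j = i + 1
        if v[j] == v[i] and gly[j] == gly[i] and nfa[j] == nfa[i]:
            while (j < n_t and v[j] == v[i] and gly[j] == gly[i]
                   and nfa[j] == nfa[i]):
                j += 1
            Q = _rate_matrix_fast(scheme, arrays, v[i], gly[i], nfa[i])
            dts = (np.arange(1, j - i)) * dt
            p[i + 1:j] = _propagate_constant(Q, p[i], dts)
            i = j - 1
        else:
            vm = 0.5 * (v[i] + v[i + 1])
            Q = _rate_matrix_fast(scheme, arrays, vm, gly[i], nfa[i])
            p[i + 1] = _propagate_constant(Q, p[i], np.array([dt]))[0]
            i += 1
    s = p.sum(axis=1, keepdims=True)
    return t, p / s


def _driving_scale(v: np.ndarray, e_rev: float) -> np.ndarray:
    """Linear unitary-current scale anchored at -30 mV."""
    return (v - e_rev) / (-30.0 - e_rev)


def _render_sweep(scheme: KineticScheme, t: np.ndarray, p: np.ndarray,
                  v: np.ndarray, vprot: VoltageProtocol, sprot: SolutionProtocol,
                  config: RecordingConfig, rng: np.random.Generator,
                  imax_scale: float, sweep_scale: float,
                  meta: dict | None) -> CurrentTrace:
    g_cond = p @ scheme.conductances
    rect = scheme.gating.rectification
    rfac = rect.factor(v) if rect is not None else 1.0
    clean = (config.n_channels * config.unitary_current_at_minus30
             * _driving_scale(v, config.e_rev) * rfac * g_cond
             * imax_scale * sweep_scale)
    noisy = clean
    if config.noise_cv > 0:
        noisy = noisy * (1.0 + config.noise_cv * rng.standard_normal(len(t)))
    if config.noise_sd > 0:
        noisy = noisy + config.noise_sd * rng.standard_normal(len(t))
    m = {"e_rev": config.e_rev, "sample_rate": vprot.sample_rate,
         "voltage_segments": list(vprot.segments),
         "solution_windows": list(sprot.windows),
         "noise_sd": config.noise_sd, "noise_cv": config.noise_cv}
    if meta:
        m.update(meta)
    return CurrentTrace(time_s=t, current_pA=noisy, voltage_mV=v, meta=m)


def simulate_whole_cell(scheme: KineticScheme, vprot: VoltageProtocol,
                        sprot: SolutionProtocol, config: RecordingConfig,
                        rng: np.random.Generator | None = None,
                        imax_scale: float = 1.0, sweep_scale: float = 1.0,
                        meta: dict | None = None) -> CurrentTrace:
    """Forward-model a whole-cell sweep; deterministic given the RNG state."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t, p = occupancy_along(scheme, vprot, sprot)
    v = vprot.voltage(t)
    return _render_sweep(scheme, t, p, v, vprot, sprot, config, rng,
                         imax_scale, sweep_scale, meta)


def simulate_single_channel(scheme: KineticScheme, v_hold: float, agonist: float,
                            blocker: float, duration: float,
                            config: RecordingConfig,
                            rng: np.random.Generator | None = None):
    """Exact stochastic simulation of one channel at fixed potential.

    Returns (events, trace): events is a list of (state name, dwell s) in
    simulated order; the trace renders events at the configured sample rate
    with amplitude i(-30) * driving-force scale * g(state) plus noise.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Q = scheme.rate_matrix(v_hold, agonist, blocker)
    n = scheme.n_states
    p0 = np.array(list(equilibrium_occupancy(scheme, v_hold, agonist, blocker).values()))
    state = int(rng.choice(n, p=p0))
    t_now = 0.0
    events: list[tuple[str, float]] = []
    names = scheme.state_names
    while t_now < duration:
        out_rates = Q[state].copy()
        out_rates[state] = 0.0
        total = out_rates.sum()
        if total <= 0:
            dwell = duration - t_now
            events.append((names[state], dwell))
            break
        dwell = rng.exponential(1.0 / total)
        dwell = min(dwell, duration - t_now)
        events.append((names[state], dwell))
        t_now += dwell
        state = int(rng.choice(n, p=out_rates / total))

    amp_state = (config.unitary_current_at_minus30
                 * _driving_scale(np.array([v_hold]), config.e_rev)[0]
                 * scheme.conductances)
    n_samp = int(round(duration * config.sample_rate))
    tgrid = np.arange(n_samp) / config.sample_rate
    edges = np.cumsum([d for _, d in events])
    idx = np.searchsorted(edges, tgrid, side="right")
    idx = np.clip(idx, 0, len(events) - 1)
    state_idx = np.array([names.index(s) for s, _ in events])
    clean = amp_state[state_idx[idx]]
    noisy = clean + config.noise_sd * rng.standard_normal(n_samp)
    trace = CurrentTrace(time_s=tgrid, current_pA=noisy, voltage_mV=np.full(n_samp, v_hold),
                         meta={"v_hold": v_hold, "glycine_uM": agonist,
                               "nfa_uM": blocker, "single_channel": True,
                               "sample_rate": config.sample_rate,
                               "noise_sd": config.noise_sd,
                               "unitary_amplitude_pA": float(abs(amp_state).max())})
    return events, trace


@dataclass
class CellRecording:
    """All sweeps from one synthetic cell plus its quality metadata."""

    cell_id: str
    imax_scale: float
    rin_mohm: float
    run_down: float
    ramp_sweeps: list = field(default_factory=list)   # dicts: conc, direction, control, drug
    long_sweeps: list = field(default_factory=list)   # dicts: conc, v_hold, trace


@dataclass
class SyntheticCohort:
    """Cells plus the generating ground truth; regenerable from (config, seed)."""

    cells: list[CellRecording]
    truth: dict
    config: RecordingConfig
    conc_grid: list[float]
    voltages: list[float]

    def manifest(self) -> str:
        return json.dumps({
            "seed": self.config.seed,
            "config": asdict(self.config),
            "truth": self.truth,
            "conc_grid": list(self.conc_grid),
            "voltages": list(self.voltages),
            "cells": [{"cell_id": c.cell_id, "imax_scale": c.imax_scale,
                       "rin_mohm": c.rin_mohm, "run_down": c.run_down,
                       "n_ramp_sweeps": len(c.ramp_sweeps),
                       "n_long_sweeps": len(c.long_sweeps)}
                      for c in self.cells],
        }, indent=1, sort_keys=True)


DEFAULT_VOLTAGE_GRID = (-80.0, -70.0, -50.0, -30.0, 30.0, 50.0, 70.0, 80.0)


def generate_cohort(n_cells: int, truth: KineticScheme, conc_grid: Sequence[float],
                    config: RecordingConfig,
                    voltages: Sequence[float] = DEFAULT_VOLTAGE_GRID,
                    glycine_uM: float = 30.0,
                    long_holds: Sequence[float] = (-30.0, 30.0),
                    include_long: bool = True) -> SyntheticCohort:
    """Per cell: control+drug ramp pairs at each blocker concentration and
    long-protocol sweeps, with drawn amplitude and quality metadata.

    All randomness flows from ``config.seed`` through per-cell child streams,
    so the same (config, seed) regenerates the cohort bit-identically.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(conc_grid) == 0 or len(voltages) == 0:
        raise ValueError("concentration and voltage grids must be non-empty")
    if any(c <= 0 for c in conc_grid):
        raise ValueError("blocker concentrations must be positive")

    ss = np.random.SeedSequence(config.seed)
    cell_seeds = ss.spawn(n_cells)

    # state occupancies depend only on (protocol, concentration), not on the
    # cell, so integrate each condition once and render per cell with its own
    # amplitude/noise stream
    ramp_cache: dict[tuple[str, float], tuple] = {}
    for direction in ("up", "down"):
        vprot = make_ramp_protocol(direction, sample_rate=config.sample_rate)
        for conc in [0.0, *conc_grid]:
            sprot = SolutionProtocol(windows=((vprot.total_duration, glycine_uM, conc),))
            t, p = occupancy_along(truth, vprot, sprot)
            ramp_cache[(direction, conc)] = (t, p, vprot.voltage(t), vprot, sprot)
    long_cache: dict[tuple[float, float], tuple] = {}
    if include_long:
        for v_hold in long_holds:
            for conc in conc_grid:
                sprot = make_long_protocol(glycine_uM, conc)
                vprot = VoltageProtocol(segments=((sprot.total_duration, v_hold, v_hold),),
                                        sample_rate=config.sample_rate)
                t, p = occupancy_along(truth, vprot, sprot)
                long_cache[(v_hold, conc)] = (t, p, vprot.voltage(t), vprot, sprot)

    cells = []
    sigma = np.sqrt(np.log1p(config.imax_cell_cv ** 2))
    for ci in range(n_cells):
        rng = np.random.default_rng(cell_seeds[ci])
        imax_scale = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        rin = float(max(10.0, rng.normal(config.rin_mean_mohm, config.rin_sd_mohm)))
        run_down_frac = float(min(0.5, abs(rng.normal(0.08, 0.05))))
        cell = CellRecording(cell_id=f"cell{ci:02d}", imax_scale=imax_scale,
                             rin_mohm=rin, run_down=run_down_frac)
        sweep = 0
        n_sweeps_total = 2 * 2 * len(conc_grid) + (2 * len(conc_grid) if include_long else 0)

        def sweep_scale(s):
            return 1.0 - run_down_frac * s / max(1, n_sweeps_total - 1)

        for direction in ("up", "down"):
            for conc in conc_grid:
                t, p, v, vprot, sprot0 = ramp_cache[(direction, 0.0)]
                ctrl = _render_sweep(truth, t, p, v, vprot, sprot0, config, rng,
                                     imax_scale, sweep_scale(sweep),
                                     meta={"cell_id": cell.cell_id, "direction": direction,
                                           "nfa_uM": 0.0, "glycine_uM": glycine_uM,
                                           "sweep": sweep})
                t, p, v, vprot, sprot = ramp_cache[(direction, conc)]
                drug = _render_sweep(truth, t, p, v, vprot, sprot, config, rng,
                                     imax_scale, sweep_scale(sweep + 1),
                                     meta={"cell_id": cell.cell_id, "direction": direction,
                                           "nfa_uM": conc, "glycine_uM": glycine_uM,
                                           "sweep": sweep + 1})
                sweep += 2
                cell.ramp_sweeps.append({"conc": conc, "direction": direction,
                                         "control": ctrl, "drug": drug})
        if include_long:
            for v_hold in long_holds:
                for conc in conc_grid:
                    t, p, v, vprot, sprot = long_cache[(v_hold, conc)]
                    tr = _render_sweep(truth, t, p, v, vprot, sprot, config, rng,
                                       imax_scale, sweep_scale(sweep),
                                       meta={"cell_id": cell.cell_id, "v_hold": v_hold,
                                             "nfa_uM": conc, "glycine_uM": glycine_uM,
                                             "sweep": sweep})
                    sweep += 1
                    cell.long_sweeps.append({"conc": conc, "v_hold": v_hold, "trace": tr})
        cells.append(cell)

    return SyntheticCohort(cells=cells, truth=json.loads(truth.to_json()),
                           config=config, conc_grid=list(conc_grid),
                           voltages=list(voltages))
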