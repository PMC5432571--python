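"""Gating plus open-channel-block kinetics with Woodhull voltage dependence.

The model is a small continuous-time Markov chain: a closed state C, an open
state O reached through agonist gating, and one or two blocked states entered
from O by the charged blocker.  Binding inside the membrane field makes the
dissociation constant voltage dependent,

    Kd(V) = Kd(0) * exp(-delta * F * V / (R * T)),

where ``delta`` is the fractional electrical distance of the site measured
from the external membrane surface.  With this sign convention (V = inside
minus outside) an anionic blocker entering from the outside binds more tightly
at depolarized potentials, which is what the whole analysis chain measures.

Everything downstream (synthetic traces, Hill fits, Woodhull regression) is
checked against the analytic equilibrium computed here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, rt_f_mV

__all__ = [
    "BlockParams",
    "GatingParams",
    "Rectification",
    "KineticScheme",
    "Transition",
    "woodhull_kd",
    "build_block_scheme",
    "equilibrium_occupancy",
    "fraction_current",
]


def woodhull_kd(kd0: float, delta: float, v_mV: float, T: float = DEFAULT_TEMPERATURE):
    """Voltage-dependent dissociation constant Kd(V) = Kd0 exp(-delta F V / RT).

    Parameters are the zero-voltage Kd (uM), the fractional electrical
    distance ``delta`` in [0, 1], the membrane potential in mV and the
    absolute temperature in K.  Accepts array-valued ``v_mV``.
    """
    v = np.asarray(v_mV, dtype=float)
    if not np.all(np.isfinite(kd0)) or not np.all(np.isfinite(delta)) or not np.all(np.isfinite(v)):
        raise ValueError("woodhull_kd: inputs must be finite")
    if not kd0 > 0:
        raise ValueError(f"woodhull_kd: Kd0 must be positive, got {kd0}")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"woodhull_kd: delta must lie in [0, 1], got {delta}")
    out = kd0 * np.exp(-delta * v / rt_f_mV(T))
    return float(out) if np.isscalar(v_mV) else out


@dataclass(frozen=True)
class BlockParams:
    """Open-channel blocker parameters.

    ``kd0`` is the per-site dissociation constant at 0 mV (uM); ``delta`` the
    fractional electrical distance; ``koff0`` the zero-voltage unblocking rate
    (s^-1), so kon0 = koff0/kd0 (uM^-1 s^-1).  ``voltage_split`` places that
    fraction of the Woodhull factor on the association rate and the rest on
    dissociation; the equilibrium is split-invariant, the kinetics are not.
    For ``n_sites=2`` the second site binds with affinity kd0/cooperativity
    and the singly-occupied state conducts with relative conductance
    ``conductance_singly_blocked`` (default 1: only double occupancy blocks).
    """

    n_sites: int = 1
    kd0: float = 100.0
    delta: float = 0.5
    koff0: float = 300.0
    voltage_split: float = 0.5
    conductance_singly_blocked: float = 1.0
    cooperativity: float = 1.0

    def __post_init__(self):
        if self.n_sites not in (1, 2):
            raise ValueError(f"n_sites must be 1 or 2, got {self.n_sites}")
        if not (self.kd0 > 0 and self.koff0 > 0):
            raise ValueError("kd0 and koff0 must be positive")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if not 0.0 <= self.voltage_split <= 1.0:
            raise ValueError("voltage_split must lie in [0, 1]")
        if not 0.0 <= self.conductance_singly_blocked <= 1.0:
            raise ValueError("conductance_singly_blocked must lie in [0, 1]")
        if not self.cooperativity > 0:
            raise ValueError("cooperativity must be positive")

    @property
    def kon0(self) -> float:
        """Association rate at 0 mV (uM^-1 s^-1) per site."""
        return self.koff0 / self.kd0


@dataclass(frozen=True)
class Rectification:
    """Boltzmann modulation of the conducting current.

    factor(V) = floor + (1-floor) / (1 + exp((v_half - V)/slope)) for outward
    rectifiers (larger current at positive V); the sign of ``slope`` is
    flipped for inward rectifiers.  The factor lies in (0, 1] and multiplies
    the conducting occupancy identically in control and drug sweeps, so it
    cancels in fraction-remaining ratios.
    """

    v_half: float = 0.0
    slope: float = 40.0
    direction: Literal["outward", "inward"] = "outward"
    floor: float = 0.25

    def factor(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        s = self.slope if self.direction == "outward" else -self.slope
        b = 1.0 / (1.0 + np.exp((self.v_half - v) / s))
        out = self.floor + (1.0 - self.floor) * b
        return float(out) if np.isscalar(v_mV) else out


@dataclass(frozen=True)
class GatingParams:
    """Agonist gating collapsed to one concentration-dependent opening rate.

    opening rate = beta0 * h([glycine]) with the saturating occupancy factor
    h(a) = a^n / (a^n + EC50^n); closing rate alpha is constant.  Optional
    desensitization appends a slowly recovering desensitized state.
    """

    opening_rate0: float = 300.0
    closing_rate: float = 50.0
    ec50_gate: float = 40.0
    n_gate: float = 1.0
    rectification: Rectification | None = None
    desensitization_rate: float = 0.0
    resensitization_rate: float = 0.5

    def __post_init__(self):
        if min(self.opening_rate0, self.closing_rate, self.desensitization_rate,
               self.resensitization_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not (self.ec50_gate > 0 and self.n_gate > 0):
            raise ValueError("ec50_gate and n_gate must be positive")

    def h(self, agonist_uM):
        """Saturating agonist-occupancy factor in [0, 1)."""
        a = np.asarray(agonist_uM, dtype=float)
        with np.errstate(invalid="ignore"):
            out = np.where(a > 0, a**self.n_gate / (a**self.n_gate + self.ec50_gate**self.n_gate), 0.0)
        return float(out) if np.isscalar(agonist_uM) else out


@dataclass(frozen=True)
class Transition:
    """One directed transition: rate = base * ligand factor * Woodhull factor.

    ``ligand`` is None, 'blocker' (rate scales with [blocker] in uM) or
    'agonist' (rate scales with the saturating factor h([agonist])).
    ``wood_coef`` multiplies V/(RT/F) inside an exponential, e.g. +s*delta
    for association and -(1-s)*delta for dissociation.
    """

    frm: str
    to: str
    base: float
    ligand: str | None = None
    wood_coef: float = 0.0


@dataclass
class KineticScheme:
    """States with conductance weights plus voltage/ligand-dependent rates."""

    states: list[tuple[str, float]]
    transitions: list[Transition]
    gating: GatingParams
    block: BlockParams
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        names = [s for s, _ in self.states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        self._index = {s: i for i, (s, _) in enumerate(self.states)}
        for tr in self.transitions:
            if tr.frm not in self._index or tr.to not in self._index:
                raise ValueError(f"transition {tr.frm}->{tr.to} references unknown state")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [s for s, _ in self.states]

    @property
    def conductances(self) -> np.ndarray:
        return np.array([g for _, g in self.states])

    def index(self, state: str) -> int:
        return self._index[state]

    def transition_rate(self, tr: Transition, v_mV: float, agonist: float, blocker: float) -> float:
        r = tr.base
        if tr.ligand == "blocker":
            r *= blocker
        elif tr.ligand == "agonist":
            r *= self.gating.h(agonist)
        if tr.wood_coef != 0.0:
            r *= math.exp(tr.wood_coef * v_mV / rt_f_mV(self.T))
        return r

    def rate_matrix(self, v_mV: float, agonist: float, blocker: float) -> np.ndarray:
        """Generator matrix Q with Q[i, j] the i->j rate and rows summing to 0."""
        if agonist < 0 or blocker < 0:
            raise ValueError("concentrations must be non-negative")
        n = self.n_states
        Q = np.zeros((n, n))
        for tr in self.transitions:
            Q[self._index[tr.frm], self._index[tr.to]] += self.transition_rate(
                tr, v_mV, agonist, blocker)
        Q[np.diag_indices(n)] -= Q.sum(axis=1)
        return Q

    def to_json(self) -> str:
        payload = {
            "states": [[s, g] for s, g in self.states],
            "transitions": [asdict(t) for t in self.transitions],
            "params": {"gating": asdict(self.gating), "block": asdict(self.block)},
            "constants": {"T": self.T},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        d = json.loads(text)
        gp = dict(d["params"]["gating"])
        rect = gp.pop("rectification", None)
        gating = GatingParams(**gp, rectification=Rectification(**rect) if rect else None)
        block = BlockParams(**d["params"]["block"])
        return cls(
            states=[(s, g) for s, g in d["states"]],
            transitions=[Transition(**t) for t in d["transitions"]],
            gating=gating,
            block=block,
            T=d["constants"]["T"],
        )


def build_block_scheme(n_sites: int, gating: GatingParams, block: BlockParams,
                       T: float = DEFAULT_TEMPERATURE) -> KineticScheme:
    """Assemble the gating + open-channel-block scheme.

    n_sites=1: C <-> O <-> OB with g(OB)=0.
    n_sites=2: C <-> O <-> OB <-> OB2 with statistical factors 2/1 on entry and
    1/2 on exit, g(OB)=block.conductance_singly_blocked, g(OB2)=0.  A
    desensitized state D is appended when gating.desensitization_rate > 0.
    """
    if n_sites not in (1, 2):
        raise ValueError(f"n_sites must be 1 or 2, got {n_sites}")
    if block.n_sites != n_sites:
        block = BlockParams(**{**asdict(block), "n_sites": n_sites})
    s = block.voltage_split
    d = block.delta
    states: list[tuple[str, float]] = [("C", 0.0), ("O", 1.0)]
    transitions = [
        Transition("C", "O", gating.opening_rate0, ligand="agonist"),
        Transition("O", "C", gating.closing_rate),
    ]
    if n_sites == 1:
        states.append(("OB", 0.0))
        transitions += [
            Transition("O", "OB", block.kon0, ligand="blocker", wood_coef=+s * d),
            Transition("OB", "O", block.koff0, wood_coef=-(1.0 - s) * d),
        ]
    else:
        states += [("OB", block.conductance_singly_blocked), ("OB2", 0.0)]
        transitions += [
            Transition("O", "OB", 2.0 * block.kon0, ligand="blocker", wood_coef=+s * d),
            Transition("OB", "O", block.koff0, wood_coef=-(1.0 - s) * d),
            Transition("OB", "OB2", block.kon0 * block.cooperativity,
                       ligand="blocker", wood_coef=+s * d),
            Transition("OB2", "OB", 2.0 * block.koff0, wood_coef=-(1.0 - s) * d),
        ]
    if gating.desensitization_rate > 0:
        states.append(("D", 0.0))
        transitions += [
            Transition("O", "D", gating.desensitization_rate),
            Transition("D", "O", gating.resensitization_rate),
        ]
    return KineticScheme(states=states, transitions=transitions, gating=gating,
                         block=block, T=T)


def equilibrium_occupancy(scheme: KineticScheme, v_mV: float, agonist: float,
                          blocker: float) -> dict[str, float]:
    """Stationary distribution of the scheme's master equation.

    Solves p Q = 0 with sum(p) = 1 by least squares on the augmented system;
    raises if the rate matrix is degenerate (disconnected graph).
    """
    Q = scheme.rate_matrix(v_mV, agonist, blocker)
    n = scheme.n_states
    A = np.vstack([Q.T, np.ones(n)])
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(Q).max())) < n:
        raise ValueError("degenerate rate matrix: stationary distribution is "
                         "not unique (transition graph disconnected?)")
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.abs(A @ p - b).max()
    if resid > 1e-8 or np.any(p < -1e-9):
        raise ValueError(f"degenerate rate matrix (residual {resid:.2e})")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return dict(zip(scheme.state_names, p))


def fraction_current(scheme: KineticScheme, v_mV: float, agonist: float,
                     blocker: float) -> float:
    """Conducting occupancy with blocker relative to blocker-free control.

    This is the equilibrium quantity the Hill inhibition equation is fitted
    to: sum_i g_i p_i(blocker) / sum_i g_i p_i(0).
    """
    g = scheme.conductances
    p_ctrl = np.array(list(equilibrium_occupancy(scheme, v_mV, agonist, 0.0).values()))
    denom = float(g @ p_ctrl)
    if denom <= 1e-12:
        raise ValueError("no conducting occupancy in control (agonist absent?)")
    p_drug = np.array(list(equilibrium_occupancy(scheme, v_mV, agonist, blocker).values()))
    return float(g @ p_drug) / denom
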