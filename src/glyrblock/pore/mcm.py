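"""Monte-Carlo energy minimization (MCM).

The classic trajectory strategy: random perturbation of the degrees of
freedom, local energy minimization, Metropolis acceptance of the minimized
energy, repeated until ``stop_after`` consecutive minimizations fail to
improve the best energy found.  The best-so-far trace is monotonically
non-increasing by construction and is returned for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

__all__ = ["MCMResult", "mc_minimize"]

KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant in kcal/mol/K


@dataclass
class MCMResult:
    """Outcome of one MCM run."""

    best_x: np.ndarray
    best_energy: float
    n_minimizations: int
    n_accepted: int
    best_trace: np.ndarray      # best-so-far after each minimization
    terminated_by_stop_rule: bool


def mc_minimize(energy: Callable[[np.ndarray], float], x0: np.ndarray,
                perturb: Callable[[np.ndarray, np.random.Generator], np.ndarray],
                seed: int | np.random.Generator = 0,
                stop_after: int = 100,
                temperature_K: float = 600.0,
                max_minimizations: int = 5000,
                minimizer_options: dict | None = None,
                minimize_indices=None,
                improvement_tol: float = 0.01) -> MCMResult:
    """MCM loop over an arbitrary objective.

    ``perturb(x, rng)`` proposes a new start from the current accepted
    point; each proposal is locally minimized (L-BFGS-B, numerical
    gradients) and accepted by the Metropolis criterion at
    ``temperature_K``.  The run stops when ``stop_after`` consecutive
    minimizations fail to lower the best energy (or at
    ``max_minimizations`` as a safety valve).

    ``minimize_indices`` restricts the gradient minimization to a subset of
    the dof vector (e.g. the ligand pose), leaving the rest to the Monte
    Carlo moves alone.  A minimization counts as improving only when it
    lowers the best energy by more than ``improvement_tol`` (kcal/mol).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kt = KCAL_PER_MOL_K * temperature_K
    opts = {"maxiter": 40, "maxfun": 2000, "eps": 1e-3}
    if minimizer_options:
        opts.update(minimizer_options)

    if minimize_indices is None:
        def local_min(x):
            res = minimize(energy, x, method="L-BFGS-B", options=opts)
            return res.x, float(res.fun)
    else:
        idx = np.asarray(minimize_indices, dtype=int)

        def local_min(x):
            x = np.asarray(x, dtype=float)

            def sub_energy(xi):
                y = x.copy()
                y[idx] = xi
                return energy(y)

            res = minimize(sub_energy, x[idx], method="L-BFGS-B", options=opts)
            out = x.copy()
            out[idx] = res.x
            return out, float(res.fun)

    x_cur, e_cur = local_min(np.asarray(x0, dtype=float))
    best_x, best_e = x_cur.copy(), e_cur
    trace = [best_e]
    fails = 0
    n_min = 1
    n_acc = 1
    while fails < stop_after and n_min < max_minimizations:
        x_try, e_try = local_min(perturb(x_cur, rng))
        n_min += 1
        if e_try < best_e - improvement_tol:
            best_x, best_e = x_try.copy(), e_try
            fails = 0
        else:
            fails += 1
        trace.append(best_e)
        if e_try <= e_cur or rng.random() < np.exp(-(e_try - e_cur) / kt):
            x_cur, e_cur = x_try, e_try
            n_acc += 1
    return MCMResult(best_x=best_x, best_energy=best_e, n_minimizations=n_min,
                     n_accepted=n_acc, best_trace=np.array(trace),
                     terminated_by_stop_rule=fails >= stop_after)
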