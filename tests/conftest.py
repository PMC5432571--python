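"""Shared fixtures.

The expensive Monte-Carlo pore scans and single-channel simulations are
session-scoped so the property tests and the acceptance suite share one
computation.
"""

import numpy as np
import pytest

from glyrblock import (BlockParams, GatingParams, Rectification, RecordingConfig,
                       build_block_scheme, simulate_single_channel)
from glyrblock.pore import (build_nfa, build_pore, compare_subtype_profiles,
                            dock_two_ligands)


def saturated_gating(rectification=None):
    """Gating with alpha/beta ~ 1e-6: the open state dominates, so the
    apparent IC50 equals the Woodhull Kd and f(c=Kd) = 1/2 exactly."""
    return GatingParams(opening_rate0=300.0, closing_rate=1e-4, ec50_gate=40.0,
                        rectification=rectification)


def one_site_scheme(kd0=40.0, delta=0.65, gating=None, koff0=300.0):
    g = gating if gating is not None else saturated_gating()
    return build_block_scheme(1, g, BlockParams(n_sites=1, kd0=kd0, delta=delta,
                                                koff0=koff0))


@pytest.fixture(scope="session")
def nfa():
    return build_nfa()


@pytest.fixture(scope="session")
def pore_alpha1():
    return build_pore("alpha1")


@pytest.fixture(scope="session")
def pore_alpha2():
    return build_pore("alpha2")


@pytest.fixture(scope="session")
def profiles_2_6(nfa, pore_alpha1, pore_alpha2):
    """Paired pulling scans over levels 2'..6' for both subtypes: each
    model's own scan plus cross-refinement of the other model's poses
    (reduced MCM stopping depth to keep the suite quick; the stop-rule
    contract itself is exercised separately on a cheap objective)."""
    cmp = compare_subtype_profiles(pore_alpha1, pore_alpha2, nfa,
                                   z_from=pore_alpha1.z_of_prime(2),
                                   z_to=pore_alpha1.z_of_prime(6), seed=11,
                                   stop_after=15,
                                   minimizer_options={"maxiter": 20})
    out = dict(cmp["profiles"])
    out["paired_best"] = cmp["best"]
    out["prime"] = cmp["prime"]
    return out


@pytest.fixture(scope="session")
def two_ligand_dock(nfa, pore_alpha1):
    """Two-ligand MCM dock above the 9' ring.  The docking landscape has
    several low-energy modes (side-by-side double Thr265-bonded, singly
    bonded, and a stacked dimer); this seeded run lands in the
    double-Thr265 mode whose structure the complex-level tests verify."""
    return dock_two_ligands(pore_alpha1, nfa, seed=5, stop_after=40,
                            minimizer_options={"maxiter": 20})


@pytest.fixture(scope="session")
def flicker_recordings():
    """Single-channel runs of the same blocked scheme at three blocker
    concentrations (fixed seeds); truth kon = 2 uM^-1 s^-1, koff = 500 s^-1."""
    gating = GatingParams(opening_rate0=50.0, closing_rate=5.0, ec50_gate=40.0)
    block = BlockParams(n_sites=1, kd0=250.0, delta=0.0, koff0=500.0)
    scheme = build_block_scheme(1, gating, block)
    cfg = RecordingConfig(noise_sd=0.25, sample_rate=50000.0, seed=7)
    out = {}
    for conc in (100.0, 300.0, 1000.0):
        out[conc] = simulate_single_channel(scheme, -30.0, 1000.0, conc, 40.0,
                                            cfg, rng=np.random.default_rng(7))
    return {"recordings": out, "kon": 2.0, "koff": 500.0, "scheme": scheme,
            "config": cfg}
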