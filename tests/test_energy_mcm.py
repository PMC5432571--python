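"""Energy model decomposition and the MCM engine."""

import numpy as np
import pytest

from glyrblock.pore.energy import (CLASH_R, COULOMB_K, CUTOFF, EnergyModel,
                                   R_FLOOR, SWITCH_ON, VDW_PARAMS, _switch2,
                                   hbond_energy)
from glyrblock.pore.mcm import mc_minimize
from glyrblock.pore.scan import (PoseProblem, plane_constraint, pin_constraint,
                                 radial_constraint, _long_axis_upright)


def naive_pair_energy(elems_a, q_a, xa, elems_b, q_b, xb):
    """Brute-force double loop implementing the documented pair formulas."""
    vdw = elec = 0.0
    for i in range(len(xa)):
        for j in range(len(xb)):
            d = xa[i] - xb[j]
            r2 = float(d @ d)
            if r2 >= CUTOFF ** 2:
                continue
            r2 = max(r2, R_FLOOR ** 2)
            t = (CUTOFF ** 2 - r2) / (CUTOFF ** 2 - SWITCH_ON ** 2)
            t = min(max(t, 0.0), 1.0)
            sw = t * t * (3 - 2 * t)
            r0 = VDW_PARAMS[elems_a[i]][0] + VDW_PARAMS[elems_b[j]][0]
            eps = np.sqrt(VDW_PARAMS[elems_a[i]][1] * VDW_PARAMS[elems_b[j]][1])
            r6 = r2 ** 3
            vdw += eps * ((r0 ** 12) / (r6 * r6) - 2.0 * (r0 ** 6) / r6) * sw
            elec += COULOMB_K * q_a[i] * q_b[j] / r2 * sw
    return vdw, elec


class TestPairEnergies:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        elems_a = ["C", "N", "O", "H", "F"]
        elems_b = ["C", "C", "O", "N", "S", "H"]
        qa = rng.uniform(-0.5, 0.5, 5)
        qb = rng.uniform(-0.5, 0.5, 6)
        model = EnergyModel(elems_a, qa, elems_b, qb)
        for _ in range(10):
            xa = rng.uniform(-6, 6, (5, 3))
            xb = rng.uniform(-6, 6, (6, 3))
            v, e, _ = model.pair_energies(xa, xb)
            v0, e0 = naive_pair_energy(elems_a, qa, xa, elems_b, qb, xb)
            assert v == pytest.approx(v0, abs=1e-8)
            assert e == pytest.approx(e0, abs=1e-8)

    def test_pair_at_vdw_optimum_returns_minus_epsilon(self):
        model = EnergyModel(["C"], [0.0], ["C"], [0.0])
        r0 = 2 * VDW_PARAMS["C"][0]
        v, e, clash = model.pair_energies(np.zeros((1, 3)),
                                          np.array([[r0, 0.0, 0.0]]))
        assert e == 0.0 and not clash
        assert v == pytest.approx(-VDW_PARAMS["C"][1], rel=1e-9)

    def test_far_apart_groups_have_zero_energy(self):
        model = EnergyModel(["C", "O"], [0.3, -0.3], ["C", "N"], [0.1, -0.1])
        v, e, _ = model.pair_energies(np.zeros((2, 3)) + 100.0, np.zeros((2, 3)))
        assert abs(v) < 0.01 and abs(e) < 0.01

    def test_overlapping_atoms_flag_clash_with_capped_repulsion(self):
        model = EnergyModel(["C"], [0.0], ["C"], [0.0])
        v, e, clash = model.pair_energies(np.zeros((1, 3)),
                                          np.full((1, 3), 0.01))
        assert clash
        assert np.isfinite(v)

    def test_decomposition_sums_to_total(self, nfa, pore_alpha1):
        lig0 = _long_axis_upright(nfa)
        z = pore_alpha1.z_of_prime(6)
        prob = PoseProblem(pore_alpha1, [lig0],
                           [plane_constraint(z), radial_constraint(),
                            pin_constraint()], z_center=z)
        x = prob.place_n1(prob.initial_dof(), z0=z)
        bd = prob.breakdown(x)
        assert bd.total == pytest.approx(bd.vdw + bd.elec + bd.hbond
                                         + bd.torsion + bd.constraint, abs=1e-12)
        assert prob.energy(x) == pytest.approx(bd.total, abs=1e-12)


class TestHbondTerm:
    def test_optimal_linear_geometry_reaches_full_depth(self):
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        a = np.array([1.0 + 1.9, 0.0, 0.0])
        assert hbond_energy(d, h, a) == pytest.approx(-4.0, rel=1e-6)

    def test_bent_geometry_is_rejected(self):
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        a = np.array([0.5, 1.0, 0.0])   # acceptor on the donor side
        assert hbond_energy(d, h, a) == 0.0


class TestMcMinimize:
    def test_quadratic_bowl_reaches_the_optimum(self):
        target = np.array([1.5, -2.0, 0.5])

        def f(x):
            return float(((x - target) ** 2).sum())

        res = mc_minimize(f, np.zeros(3),
                          lambda x, rng: x + rng.uniform(-1, 1, 3),
                          seed=0, stop_after=5)
        assert np.allclose(res.best_x, target, atol=1e-3)
        assert res.best_energy == pytest.approx(0.0, abs=1e-6)

    def test_two_well_landscape_finds_global_well(self):
        # rugged 2-D double well: global minimum at x=+2 (value -1), local
        # at x=-2 (value -0.5), with sinusoidal corrugation
        def f(v):
            x, y = v
            return float(0.05 * (x ** 2 - 4) ** 2 - 0.25 * x
                         + 0.2 * np.sin(5 * x) + 0.5 * y ** 2)

        # exhaustive grid oracle over the domain
        xs = np.linspace(-4, 4, 400)
        glob = min(f([x, 0.0]) for x in xs)
        found = 0
        for seed in range(10):
            res = mc_minimize(f, np.array([-2.0, 1.0]),
                              lambda x, rng: x + rng.uniform(-1.5, 1.5, 2),
                              seed=seed, stop_after=30)
            if res.best_energy < glob + 0.05:
                found += 1
        assert found >= 9

    def test_stop_rule_counts_consecutive_non_improving_minimizations(self):
        # convex objective: the first minimization finds the optimum, every
        # later one fails to improve, so the run ends after exactly
        # stop_after further minimizations
        def f(x):
            return float((x ** 2).sum())

        res = mc_minimize(f, np.array([3.0]),
                          lambda x, rng: x + rng.uniform(-1, 1, 1),
                          seed=1, stop_after=100)
        assert res.terminated_by_stop_rule
        assert res.n_minimizations == 101

    def test_best_energy_trace_is_monotone_nonincreasing(self):
        def f(v):
            x, y = v
            return float(np.sin(3 * x) * np.cos(2 * y) + 0.1 * (x ** 2 + y ** 2))

        res = mc_minimize(f, np.array([2.0, 2.0]),
                          lambda x, rng: x + rng.uniform(-2, 2, 2),
                          seed=2, stop_after=40)
        assert np.all(np.diff(res.best_trace) <= 1e-12)

    def test_restricted_minimization_leaves_frozen_dofs_to_mc_moves(self):
        def f(v):
            return float((v[0] - 1.0) ** 2 + (v[1] - 2.0) ** 2)

        res = mc_minimize(f, np.zeros(2),
                          lambda x, rng: x + np.array([0.0, rng.uniform(-1, 1)]),
                          seed=3, stop_after=40, minimize_indices=[0])
        assert res.best_x[0] == pytest.approx(1.0, abs=1e-4)
        assert res.best_x[1] == pytest.approx(2.0, abs=0.2)
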