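"""Kinetic scheme and analytic equilibrium (the oracle layer)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glyrblock import (BlockParams, GatingParams, KineticScheme, PhysicalConstants,
                       build_block_scheme, equilibrium_occupancy, fraction_current,
                       rt_f_mV, woodhull_kd)
from conftest import one_site_scheme, saturated_gating


class TestPhysicalConstants:
    def test_thermal_voltage_at_room_temperature(self):
        assert rt_f_mV(295.15) == pytest.approx(25.43, abs=0.01)
        assert PhysicalConstants().rt_f_mV == pytest.approx(25.43, abs=0.01)

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            rt_f_mV(0.0)


class TestWoodhullKd:
    @pytest.mark.parametrize("kd0, delta, v, expected, tol", [
        (100.0, 0.65, 0.0, 100.0, 1e-9),       # V=0 identity
        (100.0, 0.65, 80.0, 12.95, 0.05),      # hand evaluation
        (100.0, 0.16, -80.0, 165.4, 0.5),      # hand evaluation
    ])
    def test_hand_evaluated_values(self, kd0, delta, v, expected, tol):
        assert woodhull_kd(kd0, delta, v) == pytest.approx(expected, abs=tol)

    def test_strictly_decreasing_in_voltage_for_positive_delta(self):
        v = np.linspace(-100, 100, 41)
        kd = woodhull_kd(50.0, 0.4, v)
        assert np.all(np.diff(kd) < 0)

    @pytest.mark.parametrize("bad", [
        {"kd0": -1.0}, {"kd0": 0.0}, {"delta": 1.5}, {"delta": -0.1},
        {"v_mV": np.nan}, {"kd0": np.inf},
    ])
    def test_rejects_invalid_inputs(self, bad):
        kwargs = {"kd0": 100.0, "delta": 0.5, "v_mV": 0.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            woodhull_kd(**kwargs)

    @given(st.floats(0.01, 1000), st.floats(0, 1), st.floats(-150, 150))
    @settings(max_examples=50, deadline=None)
    def test_detailed_balance_identity(self, kd0, delta, v):
        # Kd(V) * Kd(-V) == Kd0^2 for any split of the field
        assert (woodhull_kd(kd0, delta, v) * woodhull_kd(kd0, delta, -v)
                == pytest.approx(kd0 ** 2, rel=1e-9))


class TestSchemeConstruction:
    def test_one_site_scheme_has_single_nonconducting_blocked_state(self):
        sch = one_site_scheme()
        assert sch.state_names == ["C", "O", "OB"]
        g = dict(zip(sch.state_names, sch.conductances))
        assert g["OB"] == 0.0 and g["O"] == 1.0 and g["C"] == 0.0

    def test_two_site_scheme_only_doubly_occupied_state_blocks(self):
        block = BlockParams(n_sites=2, kd0=100.0, delta=0.2,
                            conductance_singly_blocked=1.0)
        sch = build_block_scheme(2, saturated_gating(), block)
        g = dict(zip(sch.state_names, sch.conductances))
        assert sch.state_names == ["C", "O", "OB", "OB2"]
        assert g["OB"] == 1.0 and g["OB2"] == 0.0

    def test_three_sites_rejected(self):
        with pytest.raises(ValueError):
            build_block_scheme(3, saturated_gating(), BlockParams())

    def test_desensitized_state_appended_when_rate_positive(self):
        g = GatingParams(opening_rate0=300.0, closing_rate=50.0,
                        desensitization_rate=1.0)
        sch = build_block_scheme(1, g, BlockParams(n_sites=1))
        assert "D" in sch.state_names

    def test_blocked_entry_rates_carry_blocker_concentration(self):
        sch = one_site_scheme()
        entries = [t for t in sch.transitions if t.to.startswith("OB")]
        assert all(t.ligand == "blocker" for t in entries)

    def test_json_roundtrip(self):
        sch = one_site_scheme()
        sch2 = KineticScheme.from_json(sch.to_json())
        assert sch2.state_names == sch.state_names
        Q1 = sch.rate_matrix(25.0, 30.0, 50.0)
        Q2 = sch2.rate_matrix(25.0, 30.0, 50.0)
        np.testing.assert_allclose(Q1, Q2)


def _oracle_stationary(Q):
    """Independent dense null-space solve of the master equation."""
    from scipy.linalg import null_space
    ns = null_space(Q.T)
    p = np.abs(ns[:, 0])
    return p / p.sum()


class TestEquilibrium:
    def test_symmetric_two_state_gives_half_occupancy(self):
        # opening = closing at h(EC50) -> p(O) = p(C)
        g = GatingParams(opening_rate0=100.0, closing_rate=50.0, ec50_gate=40.0)
        sch = build_block_scheme(1, g, BlockParams(n_sites=1))
        p = equilibrium_occupancy(sch, 0.0, 40.0, 0.0)  # h = 0.5 -> beta = alpha
        assert p["O"] == pytest.approx(0.5, abs=1e-10)
        assert p["C"] == pytest.approx(0.5, abs=1e-10)

    def test_blocker_at_kd_equalizes_open_and_blocked(self):
        sch = one_site_scheme(kd0=40.0, delta=0.65)
        kd = woodhull_kd(40.0, 0.65, 60.0)
        p = equilibrium_occupancy(sch, 60.0, 1000.0, kd)
        assert p["OB"] / p["O"] == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("v,agonist,blocker", [
        (-80.0, 30.0, 100.0), (0.0, 300.0, 10.0), (80.0, 30.0, 1000.0),
    ])
    def test_matches_independent_null_space_solve(self, v, agonist, blocker):
        block = BlockParams(n_sites=2, kd0=120.0, delta=0.3, cooperativity=5.0,
                            conductance_singly_blocked=0.4)
        sch = build_block_scheme(2, GatingParams(opening_rate0=200.0,
                                                 closing_rate=80.0), block)
        Q = sch.rate_matrix(v, agonist, blocker)
        expected = _oracle_stationary(Q)
        got = np.array(list(equilibrium_occupancy(sch, v, agonist, blocker).values()))
        np.testing.assert_allclose(got, expected, atol=1e-8)
        assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_scheme_reported(self):
        # no agonist and no open-state occupancy is fine (C absorbs), but a
        # disconnected graph must be reported
        from glyrblock.kinetics import Transition
        sch = KineticScheme(states=[("A", 0.0), ("B", 1.0), ("X", 0.0)],
                            transitions=[Transition("A", "B", 10.0),
                                         Transition("B", "A", 10.0)],
                            gating=saturated_gating(), block=BlockParams())
        with pytest.raises(ValueError):
            equilibrium_occupancy(sch, 0.0, 0.0, 0.0)


class TestFractionCurrent:
    def test_no_blocker_gives_unity(self):
        sch = one_site_scheme()
        assert fraction_current(sch, -50.0, 30.0, 0.0) == pytest.approx(1.0)

    def test_half_block_at_kd_with_saturated_gating(self):
        sch = one_site_scheme(kd0=40.0, delta=0.65)
        kd = woodhull_kd(40.0, 0.65, 80.0)
        assert fraction_current(sch, 80.0, 1000.0, kd) == pytest.approx(0.5, abs=1e-4)

    def test_two_site_enumeration_example(self):
        # macroscopic K1 = 1000, K2 = 10 at c = 100 uM:
        # f = (1 + c/K1) / (1 + c/K1 + c^2/(K1 K2)) = 0.5238
        block = BlockParams(n_sites=2, kd0=2000.0, delta=0.0, cooperativity=400.0,
                            conductance_singly_blocked=1.0)
        sch = build_block_scheme(2, saturated_gating(), block)
        assert fraction_current(sch, 0.0, 1000.0, 100.0) == pytest.approx(0.5238, abs=2e-4)

    def test_monotone_nonincreasing_in_blocker(self):
        sch = one_site_scheme(kd0=40.0, delta=0.65,
                              gating=GatingParams(opening_rate0=300.0,
                                                  closing_rate=50.0))
        for v in (-80.0, 0.0, 80.0):
            f = [fraction_current(sch, v, 30.0, c)
                 for c in np.logspace(-1, 4, 25)]
            assert np.all(np.diff(f) <= 1e-12)

    def test_equilibrium_is_invariant_to_voltage_split(self):
        for split in (0.0, 0.3, 1.0):
            block = BlockParams(n_sites=1, kd0=40.0, delta=0.65,
                                voltage_split=split)
            sch = build_block_scheme(1, saturated_gating(), block)
            assert fraction_current(sch, 60.0, 1000.0, 30.0) == pytest.approx(
                fraction_current(one_site_scheme(40.0, 0.65), 60.0, 1000.0, 30.0),
                rel=1e-9)

    def test_no_conducting_control_reported(self):
        sch = one_site_scheme()
        with pytest.raises(ValueError):
            fraction_current(sch, 0.0, 0.0, 10.0)  # agonist absent
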