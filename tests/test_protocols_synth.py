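"""Protocols and the synthetic recording generator."""

import numpy as np
import pytest

from glyrblock import (BlockParams, GatingParams, Rectification, RecordingConfig,
                       SolutionProtocol, VoltageProtocol, build_block_scheme,
                       equilibrium_occupancy, generate_cohort, make_long_protocol,
                       make_ramp_protocol, simulate_single_channel,
                       simulate_whole_cell, woodhull_kd)
from glyrblock.synth import occupancy_along
from conftest import one_site_scheme, saturated_gating


class TestRampProtocol:
    def test_hold_ramp_hold_shape(self):
        p = make_ramp_protocol("up")
        assert p.total_duration == pytest.approx(2.0)
        assert p.voltage(0.25) == pytest.approx(-80.0)
        assert p.voltage(1.0) == pytest.approx(0.0)
        assert p.voltage(1.9) == pytest.approx(80.0)

    def test_down_ramp_mirrors_up_ramp(self):
        up, down = make_ramp_protocol("up"), make_ramp_protocol("down")
        t = up.times()
        np.testing.assert_allclose(down.voltage(t), -up.voltage(t), atol=1e-9)

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            make_ramp_protocol("sideways")


class TestLongProtocol:
    def test_three_windows_with_blocker_only_in_middle(self):
        p = make_long_protocol(30.0, 300.0)
        assert p.windows == ((2.0, 30.0, 0.0), (10.0, 30.0, 300.0),
                             (5.0, 30.0, 0.0))
        assert p.total_duration == pytest.approx(17.0)

    def test_zero_blocker_is_constant_agonist(self):
        p = make_long_protocol(30.0, 0.0)
        t = np.linspace(0, 16.99, 100)
        gly, nfa = p.concentrations(t)
        assert np.all(gly == 30.0) and np.all(nfa == 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_long_protocol(-1.0, 0.0)
        with pytest.raises(ValueError):
            make_long_protocol(30.0, -5.0)


@pytest.fixture
def quiet_config():
    return RecordingConfig(noise_sd=1.0, noise_cv=0.0, seed=42)


class TestWholeCellSimulation:
    def test_no_agonist_means_noise_only(self, quiet_config):
        sch = one_site_scheme()
        vprot = make_ramp_protocol("up")
        sprot = SolutionProtocol(windows=((2.0, 0.0, 0.0),))
        tr = simulate_whole_cell(sch, vprot, sprot, quiet_config)
        assert abs(tr.current_pA.mean()) < 3 * quiet_config.noise_sd / np.sqrt(len(tr.time_s))

    def test_at_reversal_potential_only_noise_remains(self, quiet_config):
        sch = one_site_scheme()
        vprot = VoltageProtocol(segments=((1.0, 0.0, 0.0),), sample_rate=2000.0)
        sprot = SolutionProtocol(windows=((1.0, 1000.0, 0.0),))
        tr = simulate_whole_cell(sch, vprot, sprot, quiet_config)
        assert np.abs(tr.current_pA).max() < 6 * quiet_config.noise_sd

    def test_terminal_occupancy_matches_analytic_equilibrium(self):
        # long fixed-V co-application segment relaxes onto the equilibrium
        sch = one_site_scheme(kd0=40.0, delta=0.65,
                              gating=GatingParams(opening_rate0=300.0,
                                                  closing_rate=50.0))
        sprot = make_long_protocol(30.0, 100.0)
        vprot = VoltageProtocol(segments=((17.0, 30.0, 30.0),), sample_rate=2000.0)
        t, p = occupancy_along(sch, vprot, sprot)
        co_end = np.searchsorted(t, 12.0) - 1  # end of the drug window
        expected = np.array(list(equilibrium_occupancy(sch, 30.0, 30.0, 100.0).values()))
        np.testing.assert_allclose(p[co_end], expected, atol=1e-4)

    def test_rectification_factor_shapes_the_iv(self, quiet_config):
        rect = Rectification(direction="outward", slope=40.0)
        sch = one_site_scheme(gating=saturated_gating(rect))
        vprot = make_ramp_protocol("up")
        sprot = SolutionProtocol(windows=((2.0, 1000.0, 0.0),))
        tr = simulate_whole_cell(sch, vprot, sprot, quiet_config)
        i_pos = np.abs(tr.current_pA[np.abs(tr.voltage_mV - 80) < 2].mean())
        i_neg = np.abs(tr.current_pA[np.abs(tr.voltage_mV + 80) < 2].mean())
        assert i_pos > i_neg

    def test_mismatched_protocol_durations_rejected(self, quiet_config):
        sch = one_site_scheme()
        with pytest.raises(ValueError):
            simulate_whole_cell(sch, make_ramp_protocol("up"),
                                make_long_protocol(30.0, 100.0), quiet_config)


class TestSingleChannel:
    def test_open_dwell_mean_is_inverse_closing_rate(self):
        g = GatingParams(opening_rate0=50.0, closing_rate=40.0, ec50_gate=40.0)
        sch = build_block_scheme(1, g, BlockParams(n_sites=1, kd0=250.0))
        cfg = RecordingConfig(sample_rate=20000.0, seed=3)
        events, _ = simulate_single_channel(sch, -30.0, 1000.0, 0.0, 120.0, cfg)
        opens = np.array([d for s, d in events if s == "O"])
        assert len(opens) > 1000
        # 95% CI of the mean of exponential dwells
        se = opens.mean() / np.sqrt(len(opens))
        assert abs(opens.mean() - 1.0 / 40.0) < 1.96 * se + 1e-4

    def test_blocked_dwell_mean_is_inverse_koff(self):
        sch = one_site_scheme(kd0=250.0, delta=0.0, koff0=500.0,
                              gating=GatingParams(opening_rate0=50.0,
                                                  closing_rate=5.0))
        cfg = RecordingConfig(sample_rate=50000.0, seed=4)
        events, _ = simulate_single_channel(sch, -30.0, 1000.0, 300.0, 60.0, cfg)
        blocked = np.array([d for s, d in events if s == "OB"])
        assert len(blocked) > 1000
        se = blocked.mean() / np.sqrt(len(blocked))
        assert abs(blocked.mean() - 1.0 / 500.0) < 1.96 * se + 1e-5

    def test_unitary_amplitude_at_minus30_is_anchored(self):
        sch = one_site_scheme(gating=GatingParams(opening_rate0=500.0,
                                                  closing_rate=1.0))
        cfg = RecordingConfig(noise_sd=0.0, sample_rate=10000.0, seed=5)
        _, tr = simulate_single_channel(sch, -30.0, 1000.0, 0.0, 2.0, cfg)
        assert tr.meta["unitary_amplitude_pA"] == pytest.approx(2.8)
        assert np.abs(tr.current_pA).max() == pytest.approx(2.8)

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_single_channel(one_site_scheme(), -30.0, 30.0, 0.0, 0.0,
                                    RecordingConfig())

    def test_long_run_state_occupancy_matches_equilibrium(self):
        # chi-square on time-in-state fractions vs the analytic stationary law
        sch = one_site_scheme(kd0=250.0, delta=0.0, koff0=500.0,
                              gating=GatingParams(opening_rate0=50.0,
                                                  closing_rate=25.0))
        cfg = RecordingConfig(sample_rate=20000.0, seed=6)
        events, _ = simulate_single_channel(sch, -30.0, 1000.0, 200.0, 120.0, cfg)
        total = {}
        for s, d in events:
            total[s] = total.get(s, 0.0) + d
        T = sum(total.values())
        expected = equilibrium_occupancy(sch, -30.0, 1000.0, 200.0)
        # time fractions are means of many exponential sojourns; compare with
        # a generous relative band (MC error)
        for s in sch.state_names:
            assert total.get(s, 0.0) / T == pytest.approx(expected[s], rel=0.05, abs=0.01)


class TestCohort:
    def test_same_seed_regenerates_bit_identical_traces(self):
        sch = one_site_scheme(gating=GatingParams(opening_rate0=300.0,
                                                  closing_rate=50.0))
        cfg = RecordingConfig(noise_sd=2.0, noise_cv=0.05, seed=9,
                              sample_rate=500.0)
        k = dict(n_cells=2, truth=sch, conc_grid=[30.0, 300.0], config=cfg,
                 include_long=False)
        c1, c2 = generate_cohort(**k), generate_cohort(**k)
        for cell1, cell2 in zip(c1.cells, c2.cells):
            assert cell1.imax_scale == cell2.imax_scale
            for s1, s2 in zip(cell1.ramp_sweeps, cell2.ramp_sweeps):
                np.testing.assert_array_equal(s1["drug"].current_pA,
                                              s2["drug"].current_pA)
        assert c1.manifest() == c2.manifest()

    def test_truth_is_stored_with_the_data(self):
        sch = one_site_scheme()
        cfg = RecordingConfig(seed=1, sample_rate=500.0)
        c = generate_cohort(1, sch, [100.0], cfg, include_long=False)
        assert c.truth["params"]["block"]["delta"] == sch.block.delta

    @pytest.mark.parametrize("bad_kwargs", [
        {"n_cells": 0}, {"conc_grid": []}, {"conc_grid": [-5.0]},
    ])
    def test_invalid_cohort_requests_rejected(self, bad_kwargs):
        kwargs = dict(n_cells=1, truth=one_site_scheme(),
                      conc_grid=[100.0], config=RecordingConfig(sample_rate=500.0))
        kwargs.update(bad_kwargs)
        with pytest.raises(ValueError):
            generate_cohort(**kwargs)

    def test_ramp_hysteresis_vanishes_for_fast_block(self):
        # with kinetics much faster than the ramp, up and down sweeps agree
        sch = one_site_scheme(kd0=40.0, delta=0.65, koff0=2000.0)
        cfg = RecordingConfig(noise_sd=0.0, noise_cv=0.0, seed=2)
        c = generate_cohort(1, sch, [100.0], cfg, include_long=False,
                            glycine_uM=1000.0)
        from glyrblock.traces import ramp_fraction_remaining
        curves = {}
        for sweep in c.cells[0].ramp_sweeps:
            curves[sweep["direction"]] = ramp_fraction_remaining(
                sweep["control"], sweep["drug"])
        up, down = curves["up"], curves["down"]
        common = np.intersect1d(up.voltage_mV, down.voltage_mV)
        fu = [up.fraction[list(up.voltage_mV).index(v)] for v in common]
        fd = [down.fraction[list(down.voltage_mV).index(v)] for v in common]
        np.testing.assert_allclose(fu, fd, atol=5e-3)
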