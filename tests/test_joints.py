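"""Premotor nets, ring-net routing and height control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insectleg.analysis import estimate_period
from insectleg.joints import (
    JOINT_CHANNELS,
    LegContext,
    LegController,
    PmnNet,
    PmnSimulator,
    branch_drives,
    height_control,
    ring_net_output,
    step_pmn,
)
from insectleg.motivation import MotivationState

from conftest import run_pure_pilocarpine


class TestLegContext:
    def test_side_role_derived_from_turn_and_body_side(self):
        assert LegContext(leg_id="front_right", theta=75.0).side_role == "inner"
        assert LegContext(leg_id="front_left", theta=75.0).side_role == "outer"
        assert LegContext(leg_id="front_left", theta=-75.0).side_role == "inner"
        assert LegContext(leg_id="front_left").side_role == "none"

    def test_rejects_unknown_leg_and_nonfinite_angles(self):
        with pytest.raises(ValueError):
            LegContext(leg_id="tail")
        with pytest.raises(ValueError):
            LegContext(alpha_angle=float("inf"))


class TestRingNet:
    @pytest.mark.parametrize(
        "direction,alpha_angle,active",
        [
            ("FW", 15.0, ("retractor", "flexor")),
            ("BW", 15.0, ("protractor", "extensor")),
            ("FW", -15.0, ("retractor", "extensor")),
            ("BW", -15.0, ("protractor", "flexor")),
        ],
    )
    def test_straight_walking_routing(self, direction, alpha_angle, active):
        ctx = LegContext(alpha_angle=alpha_angle)
        drives = ring_net_output(ctx, direction, 20.0)
        for chan, v in drives.items():
            if chan in active:
                assert v > 0
            else:
                assert v == 0.0

    def test_curve_inner_leg_routes_to_flexor(self):
        ctx = LegContext(leg_id="front_right", theta=75.0)
        drives = ring_net_output(ctx, "FW", 20.0)
        assert drives["flexor"] > 0 and drives["extensor"] == 0.0

    def test_curve_outer_leg_routes_weakly_to_extensor(self):
        ctx = LegContext(leg_id="front_left", theta=75.0)
        drives = ring_net_output(ctx, "FW", 20.0)
        straight = ring_net_output(LegContext(leg_id="front_left"), "FW", 20.0)
        assert 0 < drives["extensor"] < 0.5 * straight["flexor"]
        assert drives["flexor"] == 0.0

    def test_outer_extensor_share_grows_with_turn_angle(self):
        ext = [ring_net_output(LegContext(leg_id="front_left", theta=th),
                               "FW", 20.0)["extensor"] for th in (30.0, 50.0, 75.0)]
        assert ext[0] <= ext[1] <= ext[2]

    def test_drives_scale_with_velocity_command(self):
        ctx = LegContext()
        full = ring_net_output(ctx, "FW", 20.0)
        half = ring_net_output(ctx, "FW", 10.0)
        assert half["retractor"] == pytest.approx(0.5 * full["retractor"])

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            ring_net_output(LegContext(), "FW", -1.0)


class TestHeightControl:
    def test_flexion_beyond_reference_lifts(self):
        lev, dep = height_control(75.0)
        assert lev > 0 and dep == 0.0

    def test_extension_below_reference_presses_down(self):
        lev, dep = height_control(45.0)
        assert lev == 0.0 and dep > 0

    def test_reference_posture_gives_equal_drives(self):
        assert height_control(60.0) == (0.0, 0.0)


class TestPmn:
    def test_no_oscillation_without_pilocarpine(self):
        # constant one-sided branch input: output settles, zero cycles in 100 s
        sim = PmnSimulator(PmnNet.from_calibration("alpha"))
        rec = sim.run(100.0, branch=(0.0, 15.0))
        trace = pd.DataFrame(rec, index=(np.arange(len(rec)) + 1) * 0.01,
                             columns=["protractor", "retractor"])
        est = estimate_period(trace, "retractor", skip=5.0)
        assert not est.oscillating
        assert trace["retractor"].iloc[-1] == pytest.approx(15.0, abs=0.5)

    def test_pilocarpine_produces_antiphase_oscillation(self, pure_pilocarpine_traces):
        trace = pure_pilocarpine_traces["gamma"]
        ef = estimate_period(trace, "flexor", skip=15.0)
        ee = estimate_period(trace, "extensor", skip=15.0)
        assert ef.oscillating and ee.oscillating
        # antiphase: both channels cycle with the same period but are
        # (almost) never strongly co-active
        assert ef.period_mean == pytest.approx(ee.period_mean, rel=0.02)

    def test_equal_inputs_give_equal_half_phases(self, pure_pilocarpine_traces):
        trace = pure_pilocarpine_traces["gamma"]
        ha = estimate_period(trace, "flexor", skip=15.0).half_phase_a
        hb = estimate_period(trace, "extensor", skip=15.0).half_phase_a
        assert abs(ha - hb) / max(ha, hb) < 0.02

    def test_cocontraction_bound_during_oscillation(self, pure_pilocarpine_traces):
        # soft WTA: product of antagonists < 10% of the larger one's
        # square for >= 90% of the cycle
        for joint, (a, b) in JOINT_CHANNELS.items():
            y = pure_pilocarpine_traces[joint][[a, b]].to_numpy()[1500:]
            larger = y.max(axis=1)
            mask = larger > 0.1 * larger.max()
            frac = np.mean(y[mask, 0] * y[mask, 1] < 0.1 * larger[mask] ** 2)
            assert frac >= 0.90, joint

    def test_half_phase_monotone_in_own_pilocarpine_input(self):
        base = run_pure_pilocarpine("gamma", pilocarpine=(5.0, 5.0))
        more = run_pure_pilocarpine("gamma", pilocarpine=(6.0, 5.0))
        h_base = estimate_period(base, "flexor", skip=15.0).half_phase_a
        h_more = estimate_period(more, "flexor", skip=15.0).half_phase_a
        assert h_more >= h_base

    def test_negative_pilocarpine_rejected(self):
        sim = PmnSimulator(PmnNet.from_calibration("alpha"))
        with pytest.raises(ValueError):
            sim.step(pilocarpine=(-1.0, 0.0))

    def test_step_pmn_returns_named_channels(self):
        sim = PmnSimulator(PmnNet.from_calibration("beta"))
        out = step_pmn(sim, (2.0, 0.0), (0.0, 0.0))
        assert set(out) == {"levator", "depressor"}

    def test_pmn_net_structure(self):
        net = PmnNet.from_calibration("alpha")
        spec = net.to_network()
        hp_units = [u.id for u in spec.units if u.has_highpass]
        assert sorted(hp_units) == sorted(net.inhibitory_units)
        assert set(net.pilocarpine_ports) <= set(spec.external_input_ports)


class TestBranchDrives:
    WALK = MotivationState(stance_active=True, velocity_command=20.0)

    def test_stand_gates_everything_off(self):
        state = MotivationState(walk_active=False, velocity_command=0.0)
        drives = branch_drives(LegContext(), state, 10.0, 0.0, 70.0)
        assert all(v == 0.0 for v in drives.values())

    def test_swing_routes_opposite_the_stance_set(self):
        ctx = LegContext()
        stance = branch_drives(ctx, self.WALK, 10.0, 0.0, 70.0)
        swing_state = MotivationState(stance_active=False, velocity_command=20.0)
        swing = branch_drives(ctx, swing_state, 0.0, 10.0, 70.0)
        assert stance["retractor"] > 0 and swing["protractor"] > 0
        assert stance["protractor"] == 0.0 and swing["retractor"] == 0.0

    def test_swing_needs_sensory_evidence(self):
        # state Swing alone (no gate activity) must not produce drive
        swing_state = MotivationState(stance_active=False, velocity_command=20.0)
        drives = branch_drives(LegContext(), swing_state, 0.0, 0.0, 70.0)
        assert all(v == 0.0 for v in drives.values())

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gamma=st.floats(20.0, 120.0),
        stance=st.booleans(),
        forward=st.booleans(),
        gate_st=st.floats(0.0, 12.0),
        gate_sw=st.floats(0.0, 12.0),
    )
    def test_drives_are_one_sided_per_antagonist_pair(self, gamma, stance,
                                                      forward, gate_st, gate_sw):
        state = MotivationState(stance_active=stance, forward_active=forward,
                                velocity_command=20.0)
        drives = branch_drives(LegContext(), state, gate_st, gate_sw, gamma)
        for a, b in JOINT_CHANNELS.values():
            assert min(drives[a], drives[b]) == 0.0


class TestLegController:
    def test_stand_state_silences_all_channels(self):
        leg = LegController(LegContext())
        stand = MotivationState(walk_active=False, velocity_command=0.0)
        for _ in range(200):
            out = leg.step(stand, 10.0, 0.0)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in out.as_dict().values())

    def test_stance_with_cs_drive_activates_retractor(self):
        leg = LegController(LegContext())
        state = MotivationState(stance_active=True, velocity_command=20.0)
        for _ in range(200):
            out = leg.step(state, 10.0, 0.0)
        assert out.retractor > 10.0 and out.protractor < 0.5
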