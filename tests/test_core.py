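"""Unit dynamics, filters and the fixed-step network engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from insectleg.core import (
    Connection,
    NetworkSpec,
    NeuronUnit,
    SimClock,
    simulate,
    step_highpass,
    step_unit,
)


def make_unit(**kw):
    kw.setdefault("id", "u")
    return NeuronUnit(**kw)


class TestStepUnit:
    def test_zero_input_zero_state_is_fixed_point(self):
        u = make_unit(time_constant_lp=0.1)
        for _ in range(100):
            assert step_unit(u, 0.0, 0.001) == 0.0

    def test_constant_input_converges_to_input_plus_bias(self):
        u = make_unit(time_constant_lp=0.05, bias=2.0)
        for _ in range(5000):
            out = step_unit(u, 7.0, 0.001)
        assert out == pytest.approx(9.0, rel=1e-6)

    def test_step_response_matches_exponential(self):
        # state after one time constant = A (1 - 1/e), within 1% at dt = tau/100
        tau, A = 0.5, 10.0
        u = make_unit(time_constant_lp=tau)
        dt = tau / 100
        for _ in range(100):
            step_unit(u, A, dt)
        assert u.internal_state == pytest.approx(A * (1 - math.exp(-1)), rel=0.01)

    def test_output_clamped_to_partially_linear_range(self):
        u = make_unit(time_constant_lp=0.05, output_ceiling=20.0)
        for _ in range(10000):
            step_unit(u, 500.0, 0.001)
        assert u.output == 20.0
        for _ in range(10000):
            step_unit(u, -500.0, 0.001)
        assert u.output == 0.0

    def test_nonfinite_input_names_the_unit(self):
        u = make_unit(id="pmn_x")
        with pytest.raises(ValueError, match="pmn_x"):
            step_unit(u, float("nan"), 0.001)


class TestHighpass:
    def hp_unit(self, tau_hp=0.2):
        return make_unit(has_highpass=True, time_constant_hp=tau_hp)

    def test_dc_rejection(self):
        u = self.hp_unit(tau_hp=0.1)
        for _ in range(5000):
            out = step_highpass(u, 5.0, 0.001)
        assert out == pytest.approx(0.0, abs=1e-6)

    def test_instantaneous_pass_of_step(self):
        u = self.hp_unit()
        assert step_highpass(u, 8.0, 0.001) == pytest.approx(8.0)

    def test_ramp_response_converges_to_slope_times_tau(self):
        s, tau_hp, dt = 3.0, 0.2, 0.0005
        u = self.hp_unit(tau_hp=tau_hp)
        out = 0.0
        for k in range(int(10 * tau_hp / dt)):
            out = step_highpass(u, s * k * dt, dt)
        assert out == pytest.approx(s * tau_hp, rel=0.02)

    def test_requires_highpass_stage(self):
        with pytest.raises(ValueError, match="high-pass"):
            step_highpass(make_unit(), 1.0, 0.001)

    def test_constructing_highpass_unit_without_time_constant_fails(self):
        with pytest.raises(ValueError):
            NeuronUnit("h", has_highpass=True)


class TestNetworkSpec:
    def test_duplicate_unit_ids_rejected(self):
        spec = NetworkSpec(units=[make_unit(id="a"), make_unit(id="a")])
        with pytest.raises(ValueError, match="duplicate"):
            spec.validate()

    def test_port_must_map_to_existing_unit(self):
        spec = NetworkSpec(units=[make_unit(id="a")],
                           external_input_ports={"p": "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            spec.validate()

    def test_json_round_trip(self):
        spec = NetworkSpec(
            units=[make_unit(id="a"),
                   make_unit(id="h", has_highpass=True, time_constant_hp=0.3)],
            connections=[Connection("a", "h", -1.5)],
            external_input_ports={"inj": "a"},
        )
        back = NetworkSpec.from_dict(spec.to_dict())
        assert back.to_dict() == spec.to_dict()


class TestSimulate:
    def test_empty_network_gives_empty_trace_of_right_length(self):
        clock = SimClock(dt=0.01, duration=1.0)
        trace = simulate(NetworkSpec(), {}, clock)
        assert len(trace) == 100 and trace.shape[1] == 0

    def test_single_unit_matches_scalar_ode_oracle(self):
        # closed form of tau x' = -x + I: x(t) = I (1 - exp(-t/tau))
        tau, I = 0.5, 12.0
        spec = NetworkSpec(units=[make_unit(id="u", time_constant_lp=tau)],
                           external_input_ports={"inj": "u"})
        clock = SimClock(dt=tau / 100, duration=2.0)
        trace = simulate(spec, {"inj": np.full(clock.n_steps, I)}, clock)
        t = trace.index.to_numpy()
        exact = I * (1 - np.exp(-t / tau))
        assert np.max(np.abs(trace["u"].to_numpy() - exact)) < 0.01 * I

    def _wta_spec(self):
        units = [make_unit(id=i) for i in ("e1", "e2", "i1", "i2")]
        conns = [Connection("e1", "i1", 1.0), Connection("e2", "i2", 1.0),
                 Connection("i1", "e2", -2.0), Connection("i2", "e1", -2.0)]
        return NetworkSpec(units=units, connections=conns,
                           external_input_ports={"d1": "e1", "d2": "e2"})

    def test_mutual_inhibition_fixed_point_matches_oracle(self):
        # independent oracle: damped iteration of the fixed-point map of
        # the continuous system (e_k = d_k - 2 clip(e_other))
        d1, d2 = 8.0, 5.0
        e = np.array([0.0, 0.0])
        for _ in range(2000):
            target = np.array([d1 - 2.0 * np.clip(e[1], 0, 100),
                               d2 - 2.0 * np.clip(e[0], 0, 100)])
            e += 0.05 * (target - e)
        expect = np.clip(e, 0, 100)
        clock = SimClock(dt=0.005, duration=5.0)
        trace = simulate(self._wta_spec(),
                         {"d1": np.full(clock.n_steps, d1),
                          "d2": np.full(clock.n_steps, d2)}, clock)
        last = trace.iloc[-1]
        assert last["e1"] == pytest.approx(expect[0], abs=0.05)
        assert last["e2"] == pytest.approx(expect[1], abs=0.05)
        # only the more strongly driven unit stays above 5% of its drive
        assert last["e1"] > 0.05 * d1
        assert last["e2"] < 0.05 * d2

    def test_missing_port_series_fails(self):
        spec = NetworkSpec(units=[make_unit(id="u")],
                           external_input_ports={"inj": "u"})
        with pytest.raises(ValueError, match="inj"):
            simulate(spec, {}, SimClock(dt=0.01, duration=0.1))

    def test_determinism_bit_for_bit(self):
        spec = self._wta_spec()
        clock = SimClock(dt=0.01, duration=2.0)
        stim = {"d1": np.linspace(0, 9, clock.n_steps),
                "d2": np.full(clock.n_steps, 4.0)}
        a = simulate(spec, stim, clock)
        b = simulate(spec, stim, clock)
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_euler_convergence_halving_dt(self):
        # traces change by < 1% RMS when dt halves (tau = 0.5 network)
        units = [make_unit(id=i, time_constant_lp=0.5) for i in ("a", "b")]
        spec = NetworkSpec(units=units,
                           connections=[Connection("a", "b", 0.8)],
                           external_input_ports={"inj": "a"})
        traces = {}
        for dt in (0.01, 0.005):
            clock = SimClock(dt=dt, duration=5.0)
            stim = np.where(clock.times() > 1.0, 10.0, 0.0)
            traces[dt] = simulate(spec, {"inj": stim}, clock)
        coarse = traces[0.01].to_numpy()
        fine = traces[0.005].to_numpy()[1::2]
        rms = np.sqrt(np.mean((coarse - fine) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(coarse ** 2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-200, 200, allow_nan=False), min_size=5, max_size=40))
    def test_outputs_stay_bounded_for_bounded_inputs(self, drive):
        spec = NetworkSpec(units=[make_unit(id="u", output_ceiling=50.0)],
                           external_input_ports={"inj": "u"})
        clock = SimClock(dt=0.01, duration=len(drive) * 0.01)
        trace = simulate(spec, {"inj": np.array(drive)}, clock)
        assert (trace["u"] >= 0).all() and (trace["u"] <= 50).all()


class TestSimClock:
    def test_duration_must_be_multiple_of_dt(self):
        with pytest.raises(ValueError):
            SimClock(dt=0.01, duration=0.505)

    def test_times_cover_duration(self):
        clock = SimClock(dt=0.01, duration=1.0)
        t = clock.times()
        assert len(t) == 100 and t[-1] == pytest.approx(1.0)
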