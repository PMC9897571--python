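"""Behavioral-state selection: bistable monopoles and sensory gating.

Three winner-take-all pairs of motivation units select the behavioural
context of the leg: Stand-Walk, Forward-Backward and Swing-Stance.
Each pair is a *bistable monopole*: two excitatory units under constant
drive, cross-coupled through two purely tonic (low-pass only)
inhibitory interneurons.  Lacking any phasic element, such a net cannot
oscillate; it latches whichever side last received the stronger input
(hysteresis resolves exact ties).

Sensory gating units (the "turquoise" layer) convert stimulus events -
load on/off, caudal/rostral femur bending sensed by campaniform
sensilla, slow femoral-chordotonal-organ ramps - into drive onto Swing
or Stance.  Tactile stimulation of the abdomen or antennae drives the
Forward or Backward unit directly.  Activation of Stand fully inhibits
the global velocity command.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import GAINS
from .core import Connection, NetworkSpec, NeuronUnit, SimClock, simulate

__all__ = [
    "MonopoleSpec",
    "MotivationState",
    "SensoryEvent",
    "EVENT_PORTS",
    "build_motivation_net",
    "initial_states",
    "events_to_port_series",
    "state_from_outputs",
    "apply_context",
    "switch_direction",
]

MONOPOLES = {
    "StandWalk": ("walk", "stand"),
    "FwBw": ("fw", "bw"),
    "SwingStance": ("swing", "stance"),
}

# event kind -> (port, weight on the event magnitude)
EVENT_PORTS: dict[str, tuple[str, float]] = {
    "abdomen_touch": ("abdomen_touch", 1.0),
    "antennae_touch": ("antennae_touch", 1.0),
    "load_on": ("load_on", 1.0),
    "load_off": ("load_off", 1.0),
    "cs_caudal_bend": ("cs_stance", 1.0),
    "cs_caudal_relax": ("cs_swing", 1.0),
    # rostral bending mirrors caudal but couples to Swing; the return
    # coupling is weak (0.5x)
    "cs_rostral_bend": ("cs_swing", 1.0),
    "cs_rostral_relax": ("cs_stance", 0.5),
    "fco_elongation_ramp": ("fco_stance", 1.0),
    "fco_shortening_ramp": ("fco_swing", 1.0),
}


@dataclass(frozen=True)
class MonopoleSpec:
    """Description of one bistable winner-take-all pair."""

    name: str
    excitatory_units: tuple[str, str]
    inhibitory_units: tuple[str, str]
    constant_drive: float


@dataclass(frozen=True)
class MotivationState:
    """Settled winners of the three monopoles plus the velocity command."""

    walk_active: bool = True
    forward_active: bool = True
    stance_active: bool = False
    velocity_command: float = 0.0

    @property
    def stand_active(self) -> bool:
        return not self.walk_active

    @property
    def backward_active(self) -> bool:
        return not self.forward_active

    @property
    def swing_active(self) -> bool:
        return not self.stance_active


@dataclass(frozen=True)
class SensoryEvent:
    """A timed stimulus interval routed into the motivation layer."""

    kind: str
    onset: float
    offset: float
    magnitude: float = GAINS["stimulus_amplitude"]
    pathway: str | None = None  # 'assistance' | 'resistance' | None

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"event {self.kind}: onset must precede offset")
        if self.magnitude < 0:
            raise ValueError(f"event {self.kind}: magnitude must be >= 0")


def build_motivation_net(gains: dict[str, float] | None = None) -> NetworkSpec:
    """Build the motivation fragment: 3 monopoles, 3 gates, velocity unit.

    A tonic drive unit feeds the Stand-Walk pair; Walk is recurrently
    coupled to the Forward/Backward and Swing/Stance pairs, so that
    winning Stand silences the whole walking system.  Returns a
    :class:`NetworkSpec` with named injection ports for every sensory
    channel.
    """
    g = {**GAINS, **(gains or {})}
    tau = g["tau_lp"]
    units: list[NeuronUnit] = [NeuronUnit("drive", bias=g["tonic_drive"], time_constant_lp=tau)]
    connections: list[Connection] = []
    w_x = g["monopole_cross_inhibition"]
    for a, b in MONOPOLES.values():
        for side in (a, b):
            units.append(NeuronUnit(f"{side}_e", time_constant_lp=tau))
            units.append(NeuronUnit(f"{side}_i", time_constant_lp=tau))
            connections.append(Connection(f"{side}_e", f"{side}_i", 1.0))
        connections.append(Connection(f"{a}_i", f"{b}_e", -w_x))
        connections.append(Connection(f"{b}_i", f"{a}_e", -w_x))
    # constant drive: tonic unit -> Stand/Walk; Walk -> the other pairs
    connections += [
        Connection("drive", "walk_e", 1.0),
        Connection("drive", "stand_e", 1.0),
    ]
    for side in ("fw", "bw", "swing", "stance"):
        connections.append(Connection("walk_e", f"{side}_e", g["walk_recurrence"]))
    # sensory gating units (turquoise layer)
    for gate in ("gate_load", "gate_stance", "gate_swing"):
        units.append(NeuronUnit(gate, time_constant_lp=tau))
    gw = g["gate_weight"]
    connections += [
        Connection("gate_load", "stance_e", gw),
        Connection("gate_stance", "stance_e", gw),
        Connection("gate_swing", "swing_e", gw),
    ]
    # global velocity command, fully inhibited by Stand
    units.append(NeuronUnit("velocity", time_constant_lp=tau))
    connections += [
        Connection("drive", "velocity", 1.0),
        Connection("stand_e", "velocity", -g["velocity_inhibition"]),
    ]
    ports = {
        "abdomen_touch": "fw_e",
        "antennae_touch": "bw_e",
        "load_on": "gate_load",
        "load_off": "gate_swing",
        "cs_stance": "gate_stance",
        "cs_swing": "gate_swing",
        "fco_stance": "gate_stance",
        "fco_swing": "gate_swing",
        "stand_cmd": "stand_e",
        "walk_cmd": "walk_e",
    }
    net = NetworkSpec(units=units, connections=connections, external_input_ports=ports)
    net.validate()
    return net


def monopole_specs(gains: dict[str, float] | None = None) -> list[MonopoleSpec]:
    g = {**GAINS, **(gains or {})}
    drive = {"StandWalk": g["tonic_drive"], "FwBw": g["tonic_drive"] * g["walk_recurrence"],
             "SwingStance": g["tonic_drive"] * g["walk_recurrence"]}
    return [
        MonopoleSpec(name, (f"{a}_e", f"{b}_e"), (f"{a}_i", f"{b}_i"), drive[name])
        for name, (a, b) in MONOPOLES.items()
    ]


def initial_states(
    direction: str = "FW", stance: bool = False, gains: dict[str, float] | None = None
) -> dict[str, float]:
    """Settled internal states for Walk active with a chosen direction.

    Experiments begin in the active state: Walk, the requested walking
    direction, and (by default) Swing are the initial winners.
    """
    g = {**GAINS, **(gains or {})}
    top = g["tonic_drive"]
    low = top * g["walk_recurrence"]
    w_x = g["monopole_cross_inhibition"]
    fw = direction.upper() == "FW"
    states = {
        "drive": top,
        "walk_e": top, "walk_i": top, "stand_e": top - w_x * top, "stand_i": 0.0,
        "velocity": top,
    }
    for side, win in (("fw", fw), ("bw", not fw), ("swing", not stance), ("stance", stance)):
        states[f"{side}_e"] = low if win else low - w_x * low
        states[f"{side}_i"] = low if win else 0.0
    return states


def events_to_port_series(
    events: list[SensoryEvent], clock: SimClock
) -> dict[str, np.ndarray]:
    """Rasterize events onto the motivation net's injection ports.

    Resistance-pathway events are deliberately not routed anywhere: fast
    fCO ramps do not reach the Swing/Stance gates.
    """
    n = clock.n_steps
    series: dict[str, np.ndarray] = {}
    for ev in events:
        if ev.pathway == "resistance":
            continue
        if ev.kind not in EVENT_PORTS:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        port, weight = EVENT_PORTS[ev.kind]
        if port not in series:
            series[port] = np.zeros(n)
        i0 = max(0, int(round(ev.onset / clock.dt)))
        i1 = min(n, int(round(ev.offset / clock.dt)))
        series[port][i0:i1] += weight * ev.magnitude
    return series


def state_from_outputs(out) -> MotivationState:
    """Decode a MotivationState from unit outputs (mapping id -> mV)."""
    return MotivationState(
        walk_active=bool(out["walk_e"] >= out["stand_e"]),
        forward_active=bool(out["fw_e"] >= out["bw_e"]),
        stance_active=bool(out["stance_e"] > out["swing_e"]),
        velocity_command=float(out["velocity"]),
    )


def apply_context(
    events: list[SensoryEvent],
    t: float,
    direction: str = "FW",
    dt: float = 0.01,
    gains: dict[str, float] | None = None,
) -> MotivationState:
    """Simulate the motivation net under the given events and read the
    settled state at time ``t``."""
    net = build_motivation_net(gains)
    clock = SimClock(dt=dt, duration=round(t / dt) * dt)
    stimuli = {p: np.zeros(clock.n_steps) for p in net.external_input_ports}
    stimuli.update(events_to_port_series(events, clock))
    trace = simulate(net, stimuli, clock, initial_states=initial_states(direction, gains=gains))
    return state_from_outputs(trace.iloc[-1])


def switch_direction(state: MotivationState, new_direction: str) -> MotivationState:
    """Flip the direction monopole; a no-op when already in that state."""
    if not state.walk_active:
        raise ValueError("direction can only be switched while Walk is active")
    fw = new_direction.upper() == "FW"
    if fw == state.forward_active:
        return state
    return replace(state, forward_active=fw)
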