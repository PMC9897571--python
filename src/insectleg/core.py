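"""Leaky-integrator neural units and a fixed-step simulation engine.

Every circuit in this package is built from the same primitive: a
rectified leaky-integrator ("non-spiking") neuron with a partially
linear output characteristic,

    tau_lp * dx/dt = -x + input + bias,      output = clamp(x, floor, ceiling)

optionally preceded by a first-order high-pass stage that gives the
unit phasic (transient-passing, DC-rejecting) behaviour:

    hp(t) = input(t) - z(t),   tau_hp * dz/dt = input - z

Networks are simulated synchronously with explicit Euler at a fixed
step: every unit's input sum is formed from the previous step's
outputs, then all units advance together.  There is no randomness
anywhere, so identical specifications and stimuli yield bit-identical
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronUnit",
    "Connection",
    "NetworkSpec",
    "SimClock",
    "CompiledNetwork",
    "step_unit",
    "step_highpass",
    "simulate",
]


@dataclass
class NeuronUnit:
    """A rectified leaky integrator, optionally with a high-pass stage.

    Activations are expressed in millivolts throughout.  ``output_floor``
    defaults to 0 mV (rectification) and ``output_ceiling`` to 100 mV,
    giving the piecewise-linear characteristic used by all units.
    """

    id: str
    time_constant_lp: float = 0.05
    bias: float = 0.0
    output_floor: float = 0.0
    output_ceiling: float = 100.0
    has_highpass: bool = False
    time_constant_hp: float | None = None
    internal_state: float = 0.0
    hp_state: float = 0.0  # low-pass memory of the high-pass stage

    def __post_init__(self) -> None:
        if self.time_constant_lp <= 0:
            raise ValueError(f"unit {self.id!r}: time_constant_lp must be > 0")
        if self.has_highpass:
            if self.time_constant_hp is None or self.time_constant_hp <= 0:
                raise ValueError(
                    f"unit {self.id!r}: high-pass units need time_constant_hp > 0"
                )

    @property
    def output(self) -> float:
        return float(
            min(max(self.internal_state, self.output_floor), self.output_ceiling)
        )


@dataclass(frozen=True)
class Connection:
    """A weighted directed connection; negative weight = inhibitory."""

    source: str
    target: str
    weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValueError(f"connection {self.source}->{self.target}: weight not finite")


@dataclass
class NetworkSpec:
    """Units, connections and named external injection ports."""

    units: list[NeuronUnit] = field(default_factory=list)
    connections: list[Connection] = field(default_factory=list)
    external_input_ports: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [u.id for u in self.units]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit ids: {dupes}")
        known = set(ids)
        for c in self.connections:
            if c.source not in known or c.target not in known:
                raise ValueError(f"connection {c.source}->{c.target} references unknown unit")
        for port, unit in self.external_input_ports.items():
            if unit not in known:
                raise ValueError(f"port {port!r} maps to unknown unit {unit!r}")

    def merge(self, other: "NetworkSpec") -> "NetworkSpec":
        merged = NetworkSpec(
            units=self.units + other.units,
            connections=self.connections + other.connections,
            external_input_ports={**self.external_input_ports, **other.external_input_ports},
        )
        merged.validate()
        return merged

    # -- JSON-compatible serialization ------------------------------------
    def to_dict(self) -> dict:
        units = []
        for u in self.units:
            d = {
                "id": u.id,
                "time_constant_lp": u.time_constant_lp,
                "bias": u.bias,
                "output_floor": u.output_floor,
                "output_ceiling": u.output_ceiling,
                "has_highpass": u.has_highpass,
            }
            if u.has_highpass:
                d["time_constant_hp"] = u.time_constant_hp
            units.append(d)
        return {
            "units": units,
            "connections": [
                {"source": c.source, "target": c.target, "weight": c.weight}
                for c in self.connections
            ],
            "ports": dict(self.external_input_ports),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        spec = cls(
            units=[NeuronUnit(**u) for u in data["units"]],
            connections=[Connection(**c) for c in data["connections"]],
            external_input_ports=dict(data.get("ports", {})),
        )
        spec.validate()
        return spec


@dataclass
class SimClock:
    """Fixed-step clock; ``duration`` must be a positive multiple of ``dt``."""

    dt: float = 0.01
    duration: float = 10.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.duration / self.dt
        if self.duration <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a positive multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def times(self) -> np.ndarray:
        """Time stamps of recorded samples (state after each step)."""
        return (np.arange(self.n_steps) + 1) * self.dt


# ---------------------------------------------------------------------------
# single-unit operations


def step_unit(unit: NeuronUnit, input_sum: float, dt: float) -> float:
    """Advance one unit by one Euler step; returns the clamped output.

    For plain units the input drives the leaky integrator directly; for
    high-pass units the input first passes the phasic stage.
    """
    if not math.isfinite(input_sum):
        raise ValueError(f"unit {unit.id!r}: non-finite input {input_sum!r}")
    if dt >= unit.time_constant_lp:
        raise ValueError(f"unit {unit.id!r}: dt must be < time_constant_lp for stability")
    drive = input_sum
    if unit.has_highpass:
        drive = input_sum - unit.hp_state
        unit.hp_state += dt / unit.time_constant_hp * (input_sum - unit.hp_state)
    unit.internal_state += dt / unit.time_constant_lp * (
        -unit.internal_state + drive + unit.bias
    )
    return unit.output


def step_highpass(unit: NeuronUnit, input_: float, dt: float) -> float:
    """One step of the phasic stage alone: input minus its low-pass memory.

    Passes transients instantaneously, rejects DC, and is rectified at
    the unit's output floor.  Only valid on units built with a
    high-pass stage.
    """
    if not unit.has_highpass:
        raise ValueError(f"unit {unit.id!r} has no high-pass stage")
    if not math.isfinite(input_):
        raise ValueError(f"unit {unit.id!r}: non-finite input {input_!r}")
    out = input_ - unit.hp_state
    unit.hp_state += dt / unit.time_constant_hp * (input_ - unit.hp_state)
    return max(out, unit.output_floor)


# ---------------------------------------------------------------------------
# network engine


class CompiledNetwork:
    """Array-compiled form of a :class:`NetworkSpec` for fast stepping.

    Update order per step (synchronous): input sums from the previous
    outputs plus external port injections; high-pass stages; leaky
    integration; clamping.
    """

    def __init__(self, spec: NetworkSpec, dt: float = 0.01):
        spec.validate()
        self.spec = spec
        self.dt = dt
        ids = [u.id for u in spec.units]
        self.index = {uid: i for i, uid in enumerate(ids)}
        self.ids = ids
        n = len(ids)
        self.n = n
        self.tau_lp = np.array([u.time_constant_lp for u in spec.units])
        if n and dt >= self.tau_lp.min():
            raise ValueError("dt must be smaller than every low-pass time constant")
        self.bias = np.array([u.bias for u in spec.units])
        self.floor = np.array([u.output_floor for u in spec.units])
        self.ceil = np.array([u.output_ceiling for u in spec.units])
        self.hp_mask = np.array([u.has_highpass for u in spec.units])
        self.tau_hp = np.array(
            [u.time_constant_hp if u.has_highpass else 1.0 for u in spec.units]
        )
        # W[i, j] = weight of connection j -> i, so inputs = W @ outputs
        self.W = np.zeros((n, n))
        for c in spec.connections:
            self.W[self.index[c.target], self.index[c.source]] += c.weight
        self.port_index = {
            port: self.index[unit] for port, unit in spec.external_input_ports.items()
        }
        self._a_lp = dt / self.tau_lp
        self._a_hp = dt / self.tau_hp
        self.reset()

    def reset(self, initial_states: dict[str, float] | None = None) -> None:
        self.x = np.zeros(self.n)
        self.z = np.zeros(self.n)
        if initial_states:
            for uid, v in initial_states.items():
                self.x[self.index[uid]] = v
        self.out = np.clip(self.x, self.floor, self.ceil)
        self.step_count = 0

    def step(self, ext: np.ndarray | None = None) -> np.ndarray:
        """Advance one step; ``ext`` is per-unit external injection (mV)."""
        inp = self.W @ self.out
        if ext is not None:
            inp = inp + ext
        drive = np.where(self.hp_mask, inp - self.z, inp)
        self.z += self._a_hp * (inp - self.z)
        self.x += self._a_lp * (-self.x + drive + self.bias)
        if not np.all(np.isfinite(self.x)):
            bad = [self.ids[i] for i in np.where(~np.isfinite(self.x))[0]]
            raise RuntimeError(
                f"non-finite state at step {self.step_count} in units {bad}"
            )
        self.out = np.clip(self.x, self.floor, self.ceil)
        self.step_count += 1
        return self.out

    def port_vector(self, port_values: dict[str, float]) -> np.ndarray:
        ext = np.zeros(self.n)
        for port, v in port_values.items():
            ext[self.port_index[port]] += v
        return ext

    def settle(self, port_values: dict[str, float] | None = None, t: float = 1.0) -> None:
        ext = self.port_vector(port_values or {})
        for _ in range(int(round(t / self.dt))):
            self.step(ext)


def simulate(
    net: NetworkSpec,
    stimuli: dict[str, np.ndarray],
    clock: SimClock,
    initial_states: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Run a network open loop and return per-unit output time series.

    ``stimuli`` maps port names to series of length ``clock.n_steps``;
    every declared port must be covered.  The result is a DataFrame
    indexed by time with one column per unit.
    """
    n_steps = clock.n_steps
    engine = CompiledNetwork(net, dt=clock.dt)
    engine.reset(initial_states)
    for port in net.external_input_ports:
        if port not in stimuli:
            raise ValueError(f"missing stimulus series for port {port!r}")
    for port, series in stimuli.items():
        if port not in engine.port_index:
            raise ValueError(f"unknown port {port!r}")
        if len(series) != n_steps:
            raise ValueError(
                f"stimulus for port {port!r} has length {len(series)}, expected {n_steps}"
            )
        if not np.all(np.isfinite(series)):
            raise ValueError(f"stimulus for port {port!r} contains non-finite values")
    ports = list(stimuli)
    idx = np.array([engine.port_index[p] for p in ports], dtype=int)
    stim = np.array([stimuli[p] for p in ports]) if ports else None
    rec = np.empty((n_steps, engine.n))
    ext = np.zeros(engine.n)
    for k in range(n_steps):
        if stim is not None:
            ext[:] = 0.0
            np.add.at(ext, idx, stim[:, k])
        rec[k] = engine.step(ext if stim is not None else None)
    return pd.DataFrame(rec, index=clock.times(), columns=engine.ids)
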