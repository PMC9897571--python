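"""Sensory and pharmacological stimulus time series.

Three generators cover all experiments: square-wave campaniform-sensilla
femur-bending protocols, trapezoidal ramp-and-hold stimulation of the
femoral chordotonal organ (fCO) apodeme, and constant per-branch
injection levels emulating pilocarpine application.

The fCO generator also implements the velocity gate of the sensory
pathway: elongation ramps at or below 2 mm/s are routed to the
assistance (active-reaction) pathway and activate state Stance, ramps
strictly faster than 6 mm/s are tagged as resistance-pathway events and
activate nothing here, and the band in between is a dead zone.  A
velocity exactly on a gate boundary falls into the slower class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FCO_FAST_GATE, FCO_SLOW_GATE, GAINS
from .core import SimClock
from .motivation import SensoryEvent

__all__ = [
    "CsProtocol",
    "FcoProtocol",
    "generate_cs",
    "generate_fco",
    "generate_pilocarpine",
]


@dataclass(frozen=True)
class CsProtocol:
    """Square-wave femur-bending protocol for the campaniform sensilla."""

    period: float = 6.0
    bend_fraction: float = 2.0 / 3.0
    amplitude: float = GAINS["stimulus_amplitude"]
    direction: str = "caudal"  # 'caudal' | 'rostral'
    n_cycles: int = 2

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if not 0.0 < self.bend_fraction < 1.0:
            raise ValueError("bend_fraction must be in (0, 1)")
        if self.direction not in ("caudal", "rostral"):
            raise ValueError("direction must be 'caudal' or 'rostral'")


@dataclass(frozen=True)
class FcoProtocol:
    """Trapezoidal ramp-and-hold stimulation of the fCO apodeme (mm)."""

    ramp_velocity: float = 1.0      # mm/s
    start_position: float = -0.25   # shortened hold level
    end_position: float = 0.25      # elongated hold level
    period: float = 6.0
    elongated_fraction: float = 2.0 / 3.0
    n_cycles: int = 2

    def __post_init__(self) -> None:
        if self.ramp_velocity <= 0:
            raise ValueError("ramp_velocity must be > 0")
        if not (np.isfinite(self.start_position) and np.isfinite(self.end_position)):
            raise ValueError("positions must be finite")
        if self.end_position <= self.start_position:
            raise ValueError("end_position must exceed start_position")
        ramp_t = (self.end_position - self.start_position) / self.ramp_velocity
        if ramp_t > min(self.elongated_fraction, 1 - self.elongated_fraction) * self.period:
            raise ValueError("ramp does not fit inside its phase of the period")


def generate_cs(protocol: CsProtocol, clock: SimClock
                ) -> tuple[np.ndarray, list[SensoryEvent]]:
    """Square-wave bending series plus the matching event list.

    Bending occupies the first ``bend_fraction`` of each cycle (4 s of a
    6 s cycle by default, enforcing Stance, followed by 2 s of
    relaxation that enforces Swing).  Zero amplitude yields an all-zero
    series and no events.
    """
    if protocol.n_cycles * protocol.period > clock.duration + 1e-9:
        raise ValueError("protocol cycles exceed the clock duration")
    series = np.zeros(clock.n_steps)
    events: list[SensoryEvent] = []
    if protocol.amplitude == 0.0:
        return series, events
    bend_kind = f"cs_{protocol.direction}_bend"
    relax_kind = f"cs_{protocol.direction}_relax"
    t = clock.times()
    for k in range(protocol.n_cycles):
        t0 = k * protocol.period
        t_mid = t0 + protocol.bend_fraction * protocol.period
        t1 = t0 + protocol.period
        series[(t > t0) & (t <= t_mid)] = protocol.amplitude
        events.append(SensoryEvent(bend_kind, t0, t_mid, protocol.amplitude))
        events.append(SensoryEvent(relax_kind, t_mid, t1, protocol.amplitude))
    return series, events


def classify_ramp_velocity(velocity: float) -> str | None:
    """Route a ramp velocity: 'assistance', 'resistance' or None (dead zone)."""
    if velocity <= FCO_SLOW_GATE:
        return "assistance"
    if velocity > FCO_FAST_GATE:
        return "resistance"
    return None


def generate_fco(protocol: FcoProtocol, clock: SimClock
                 ) -> tuple[np.ndarray, np.ndarray, list[SensoryEvent]]:
    """Trapezoidal apodeme position/velocity series plus gated events.

    Each cycle elongates from the shortened to the elongated hold level
    at ``ramp_velocity``, holds, then shortens back and holds.  When the
    velocity falls in the assistance band the elongated phase emits an
    ``fco_elongation_ramp`` event (activating Stance) and the shortened
    phase an ``fco_shortening_ramp`` event (activating Swing); in the
    resistance band the same events carry ``pathway='resistance'`` and
    are not routed to the gates.
    """
    if protocol.n_cycles * protocol.period > clock.duration + 1e-9:
        raise ValueError("protocol cycles exceed the clock duration")
    t = clock.times()
    pos = np.full(clock.n_steps, protocol.start_position)
    vel = np.zeros(clock.n_steps)
    events: list[SensoryEvent] = []
    span = protocol.end_position - protocol.start_position
    ramp_t = span / protocol.ramp_velocity
    pathway = classify_ramp_velocity(protocol.ramp_velocity)
    magnitude = GAINS["stimulus_amplitude"]
    for k in range(protocol.n_cycles):
        t0 = k * protocol.period
        t_down = t0 + protocol.elongated_fraction * protocol.period
        t1 = t0 + protocol.period
        up = (t > t0) & (t <= t0 + ramp_t)
        pos[up] = protocol.start_position + protocol.ramp_velocity * (t[up] - t0)
        vel[up] = protocol.ramp_velocity
        hold_hi = (t > t0 + ramp_t) & (t <= t_down)
        pos[hold_hi] = protocol.end_position
        down = (t > t_down) & (t <= t_down + ramp_t)
        pos[down] = protocol.end_position - protocol.ramp_velocity * (t[down] - t_down)
        vel[down] = -protocol.ramp_velocity
        hold_lo = (t > t_down + ramp_t) & (t <= t1)
        pos[hold_lo] = protocol.start_position
        if pathway is not None:
            events.append(SensoryEvent("fco_elongation_ramp", t0, t_down,
                                       magnitude, pathway=pathway))
            events.append(SensoryEvent("fco_shortening_ramp", t_down, t1,
                                       magnitude, pathway=pathway))
    return pos, vel, events


def generate_pilocarpine(config: dict[str, tuple[float, float]], clock: SimClock
                         ) -> dict[str, np.ndarray]:
    """Constant per-port injection series from scenario onset.

    ``config`` maps joint name to the (agonist, antagonist) levels in mV
    (e.g. ``{"alpha": (3.0, 6.0), ...}``).  No pharmacokinetics: the
    level is constant from t = 0.
    """
    from .joints import JOINT_CHANNELS  # local import to avoid a cycle

    series: dict[str, np.ndarray] = {}
    for joint, levels in config.items():
        a, b = JOINT_CHANNELS[joint]
        for chan, level in zip((a, b), levels):
            if level < 0:
                raise ValueError(f"pilocarpine level for {chan} must be >= 0")
            series[f"pilo_{chan}"] = np.full(clock.n_steps, float(level))
    return series
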