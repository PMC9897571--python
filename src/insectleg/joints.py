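"""Per-joint control of one leg: premotor nets, ring-net routing, height control.

Each of the three joints (alpha = thorax-coxa: protractor/retractor;
beta = coxa-trochanterofemur: levator/depressor; gamma = femur-tibia:
flexor/extensor) is driven through a four-unit premotor (PMN) soft
winner-take-all net: two excitatory branch units and two *phasic*
inhibitory units whose high-pass stage makes the lateral inhibition
transient.  The stronger branch suppresses the weaker one, which
minimises co-contraction; because the inhibition adapts away, constant
excitation of *both* branches (the simulated pilocarpine injection)
turns the net into a relaxation oscillator, whereas without that
injection it has no rhythm of its own.

The stance-direction stage ("ring net") maps leg posture, walking
direction and turning angle to the antagonist that propels the leg tip
along a straight (or curved) trajectory; the height controller maps
femur-tibia flexion onto the levator/depressor pair independently of
walking direction.  All routing delivers drive to exactly one
antagonist of a pair at any instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GAINS, PMN_CALIBRATION
from .core import Connection, NetworkSpec, NeuronUnit, CompiledNetwork
from .motivation import MotivationState

__all__ = [
    "LegContext",
    "PmnNet",
    "PmnSimulator",
    "MotorOutput",
    "JOINT_CHANNELS",
    "ring_net_output",
    "height_control",
    "swing_drives",
    "branch_drives",
    "step_pmn",
    "LegController",
]

LEG_IDS = (
    "front_left", "front_right", "middle_left", "middle_right", "hind_left", "hind_right",
)

JOINT_CHANNELS = {
    "alpha": ("protractor", "retractor"),
    "beta": ("levator", "depressor"),
    "gamma": ("flexor", "extensor"),
}
CHANNELS = tuple(c for pair in JOINT_CHANNELS.values() for c in pair)


@dataclass(frozen=True)
class LegContext:
    """Fixed posture and geometric role of the tested leg.

    ``alpha_angle`` > ``anterior_boundary`` counts as the anterior range
    of the thorax-coxa working range; ``theta`` is the turning angle in
    degrees (0 = straight, positive = right turn).  ``side_role`` is
    derived from the sign of theta and the leg's body side unless given.
    """

    leg_id: str = "middle_left"
    alpha_angle: float = 15.0
    gamma_angle: float = 70.0
    theta: float = 0.0
    side_role: str = "none"  # 'inner' | 'outer' | 'none'
    anterior_boundary: float = 0.0

    def __post_init__(self) -> None:
        if self.leg_id not in LEG_IDS:
            raise ValueError(f"unknown leg_id {self.leg_id!r}")
        if not (np.isfinite(self.alpha_angle) and np.isfinite(self.gamma_angle)
                and np.isfinite(self.theta)):
            raise ValueError("leg angles must be finite")
        if self.side_role == "none" and self.theta != 0.0:
            right = self.leg_id.endswith("right")
            inner = (self.theta > 0) == right
            object.__setattr__(self, "side_role", "inner" if inner else "outer")

    @property
    def anterior(self) -> bool:
        return self.alpha_angle >= self.anterior_boundary


@dataclass(frozen=True)
class PmnNet:
    """Premotor soft-WTA net of one joint.

    The two inhibitory units carry high-pass stages with the calibrated
    per-joint time constant; ``w_ab``/``w_ba`` are the lateral
    inhibition gains (I_a onto E_b and I_b onto E_a).  There is no
    constant excitatory input: only the branch drives and the
    pilocarpine ports excite the net.
    """

    joint: str
    hp_time_constant: float
    w_ab: float
    w_ba: float
    g_ei: float = GAINS["pmn_g_ei"]
    mn_cross: float = 0.5
    tau_lp: float = GAINS["tau_lp"]

    def __post_init__(self) -> None:
        if self.joint not in JOINT_CHANNELS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.hp_time_constant <= 0:
            raise ValueError("hp_time_constant must be > 0")

    @property
    def excitatory_units(self) -> tuple[str, str]:
        a, b = JOINT_CHANNELS[self.joint]
        return (f"{a}_pmn", f"{b}_pmn")

    @property
    def inhibitory_units(self) -> tuple[str, str]:
        a, b = JOINT_CHANNELS[self.joint]
        return (f"{a}_ipmn", f"{b}_ipmn")

    @property
    def pilocarpine_ports(self) -> tuple[str, str]:
        a, b = JOINT_CHANNELS[self.joint]
        return (f"pilo_{a}", f"pilo_{b}")

    def to_network(self) -> NetworkSpec:
        a, b = JOINT_CHANNELS[self.joint]
        ea, eb = self.excitatory_units
        ia, ib = self.inhibitory_units
        units = [
            NeuronUnit(ea, time_constant_lp=self.tau_lp),
            NeuronUnit(eb, time_constant_lp=self.tau_lp),
            NeuronUnit(ia, time_constant_lp=self.tau_lp, has_highpass=True,
                       time_constant_hp=self.hp_time_constant),
            NeuronUnit(ib, time_constant_lp=self.tau_lp, has_highpass=True,
                       time_constant_hp=self.hp_time_constant),
            NeuronUnit(f"{a}_mn", time_constant_lp=self.tau_lp),
            NeuronUnit(f"{b}_mn", time_constant_lp=self.tau_lp),
        ]
        connections = [
            Connection(ea, ia, self.g_ei),
            Connection(eb, ib, self.g_ei),
            Connection(ia, eb, -self.w_ab),
            Connection(ib, ea, -self.w_ba),
            Connection(ea, f"{a}_mn", 1.0),
            Connection(eb, f"{b}_mn", 1.0),
            # crossed premotor->motoneuron inhibition suppresses the weaker
            # branch's motor output while the winner's phase lasts
            Connection(ea, f"{b}_mn", -self.mn_cross),
            Connection(eb, f"{a}_mn", -self.mn_cross),
        ]
        ports = {
            f"pilo_{a}": ea, f"pilo_{b}": eb,
            f"branch_{a}": ea, f"branch_{b}": eb,
        }
        net = NetworkSpec(units=units, connections=connections, external_input_ports=ports)
        net.validate()
        return net

    @classmethod
    def from_calibration(cls, joint: str,
                         calibration: dict[str, dict[str, float]] | None = None) -> "PmnNet":
        cal = (calibration or PMN_CALIBRATION)[joint]
        return cls(joint=joint, hp_time_constant=cal["tau_hp"],
                   w_ab=cal["w_ab"], w_ba=cal["w_ba"],
                   g_ei=cal.get("g_ei", GAINS["pmn_g_ei"]),
                   mn_cross=cal.get("mn_cross", 0.5))


class PmnSimulator:
    """Stateful stepper for one premotor net.

    Symmetry of the equal-drive case is broken deterministically by a
    small initial activation (0.01 mV) of the first-listed branch.
    """

    SEED_STATE = 0.01

    def __init__(self, net: PmnNet, dt: float = 0.01):
        self.net = net
        self.dt = dt
        self.engine = CompiledNetwork(net.to_network(), dt=dt)
        a, b = JOINT_CHANNELS[net.joint]
        self.channel_a, self.channel_b = a, b
        self._mn_idx = (self.engine.index[f"{a}_mn"], self.engine.index[f"{b}_mn"])
        self._port_idx = (
            self.engine.port_index[f"pilo_{a}"],
            self.engine.port_index[f"pilo_{b}"],
            self.engine.port_index[f"branch_{a}"],
            self.engine.port_index[f"branch_{b}"],
        )
        self.reset()

    def reset(self) -> None:
        self.engine.reset({f"{self.channel_a}_pmn": self.SEED_STATE})

    def step(self, branch: tuple[float, float] = (0.0, 0.0),
             pilocarpine: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
        """Advance one step; returns the two motor-neuron outputs (mV)."""
        if pilocarpine[0] < 0 or pilocarpine[1] < 0:
            raise ValueError("pilocarpine injection must be >= 0")
        ext = np.zeros(self.engine.n)
        ia, ib, ba, bb = self._port_idx
        ext[ia] += pilocarpine[0]
        ext[ib] += pilocarpine[1]
        ext[ba] += branch[0]
        ext[bb] += branch[1]
        out = self.engine.step(ext)
        return float(out[self._mn_idx[0]]), float(out[self._mn_idx[1]])

    def run(self, duration: float, branch=(0.0, 0.0), pilocarpine=(0.0, 0.0)) -> np.ndarray:
        """Run with constant inputs; returns (n_steps, 2) motor outputs."""
        n = int(round(duration / self.dt))
        rec = np.empty((n, 2))
        for k in range(n):
            rec[k] = self.step(branch, pilocarpine)
        return rec


def step_pmn(sim: PmnSimulator, branch_inputs: tuple[float, float],
             pilocarpine: tuple[float, float], dt: float | None = None) -> dict[str, float]:
    """Single premotor step returning named motor channels for the joint."""
    if dt is not None and abs(dt - sim.dt) > 1e-12:
        raise ValueError("dt must match the simulator's step size")
    out_a, out_b = sim.step(branch_inputs, pilocarpine)
    return {sim.channel_a: out_a, sim.channel_b: out_b}


@dataclass(frozen=True)
class MotorOutput:
    """Outputs of the six motor channels (mV, rectified).

    In open loop these are recorded only - they never move the leg or
    feed back into the sensors.
    """

    protractor: float = 0.0
    retractor: float = 0.0
    levator: float = 0.0
    depressor: float = 0.0
    flexor: float = 0.0
    extensor: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CHANNELS}


# ---------------------------------------------------------------------------
# stance-direction routing (ring net) and height control


def ring_net_output(ctx: LegContext, direction: str, velocity_command: float,
                    gains: dict[str, float] | None = None) -> dict[str, float]:
    """Stance drives for the alpha and gamma antagonist channels.

    Straight walking: forward -> retractor, backward -> protractor, each
    scaled by the velocity command.  The gamma side follows the posture
    rule: with the leg in the anterior range, forward walking drives the
    flexor and backward walking the extensor; in the posterior range the
    arrangement inverts.  With a non-zero turning angle the inner front
    leg routes fully to the flexor while the outer leg receives only a
    weak drive that shifts monotonically from flexor to extensor as the
    turn sharpens (fully extensor from 75 degrees).
    """
    g = {**GAINS, **(gains or {})}
    if velocity_command < 0:
        raise ValueError("velocity_command must be >= 0")
    fw = direction.upper() == "FW"
    v = velocity_command / g["tonic_drive"]
    drives = {c: 0.0 for c in ("protractor", "retractor", "flexor", "extensor")}
    drives["retractor" if fw else "protractor"] = g["stance_alpha_amp"] * v
    if ctx.theta == 0.0:
        flex_side = ctx.anterior == fw
        drives["flexor" if flex_side else "extensor"] = g["stance_gamma_amp"] * v
    else:
        if ctx.side_role not in ("inner", "outer"):
            raise ValueError("side_role undefined for theta != 0")
        if ctx.side_role == "inner":
            drives["flexor"] = g["stance_gamma_amp"] * v
        else:
            blend = min(abs(ctx.theta) / 75.0, 1.0)
            weak = g["curve_weak_amp"] * v
            drives["extensor"] = weak * blend
            drives["flexor"] = weak * (1.0 - blend)
    return drives


def height_control(gamma_angle: float, gains: dict[str, float] | None = None
                   ) -> tuple[float, float]:
    """Levator/depressor drives keeping body height against tibia flexion.

    Returns the (levator, depressor) pair proportional to the deviation
    of the femur-tibia angle from the 60-degree reference, routed to one
    side only; flexion beyond the reference lifts (levator), extension
    below it presses down (depressor).  Deliberately independent of
    walking direction.
    """
    g = {**GAINS, **(gains or {})}
    dev = g["height_gain"] * (gamma_angle - g["height_reference_deg"])
    return (max(0.0, dev), max(0.0, -dev))


def swing_drives(ctx: LegContext, direction: str, amplitude: float) -> dict[str, float]:
    """Stereotyped swing drive: the antagonists opposite the stance set."""
    fw = direction.upper() == "FW"
    drives = {c: 0.0 for c in ("protractor", "retractor", "flexor", "extensor")}
    drives["protractor" if fw else "retractor"] = amplitude
    flex_in_stance = ctx.anterior == fw
    drives["extensor" if flex_in_stance else "flexor"] = amplitude
    return drives


def branch_drives(ctx: LegContext, state: MotivationState,
                  gate_stance: float, gate_swing: float, gamma_eff: float,
                  gains: dict[str, float] | None = None) -> dict[str, float]:
    """Combine stance and swing branch inputs into per-channel drives.

    The stance branch is active while state Stance holds *and* the
    stance gate carries sensory evidence; likewise for swing.  The beta
    drive is a single signed signal - height-control deviation plus a
    levator-ward bias in swing and a depressor-ward bias in stance -
    routed to exactly one antagonist, so no constant input ever excites
    both branches of a pair at once.
    """
    g = {**GAINS, **(gains or {})}
    drives = {c: 0.0 for c in CHANNELS}
    if not state.walk_active:
        return drives
    stance_on = state.stance_active and gate_stance > 1.0
    swing_on = state.swing_active and gate_swing > 1.0
    direction = "FW" if state.forward_active else "BW"
    v = state.velocity_command
    beta_net = 0.0
    if stance_on:
        drives.update(ring_net_output(ctx, direction, v, g))
        lev, dep = height_control(gamma_eff, g)
        beta_net = (lev - dep) - g["stance_support"] * (v / g["tonic_drive"])
    elif swing_on:
        drives.update(swing_drives(ctx, direction, g["swing_amp"] * (v / g["tonic_drive"])))
        lev, dep = height_control(gamma_eff, g)
        beta_net = (lev - dep) + g["swing_lift"]
    if stance_on or swing_on:
        drives["levator"] = max(0.0, beta_net)
        drives["depressor"] = max(0.0, -beta_net)
    return drives


class LegController:
    """The three premotor nets of one leg plus branch routing.

    The controller is open loop: joint angles are part of the scenario's
    :class:`LegContext`, never updated by motor output.
    """

    def __init__(self, ctx: LegContext, dt: float = 0.01,
                 calibration: dict[str, dict[str, float]] | None = None,
                 pilocarpine: dict[str, tuple[float, float]] | None = None,
                 gains: dict[str, float] | None = None):
        self.ctx = ctx
        self.dt = dt
        self.gains = {**GAINS, **(gains or {})}
        self.pilocarpine = pilocarpine or {j: (0.0, 0.0) for j in JOINT_CHANNELS}
        self.pmns = {
            joint: PmnSimulator(PmnNet.from_calibration(joint, calibration), dt=dt)
            for joint in JOINT_CHANNELS
        }

    def reset(self) -> None:
        for sim in self.pmns.values():
            sim.reset()

    def step(self, state: MotivationState, gate_stance: float, gate_swing: float,
             gamma_eff: float | None = None) -> MotorOutput:
        """Advance all joints one step and return the motor outputs."""
        gamma = self.ctx.gamma_angle if gamma_eff is None else gamma_eff
        drives = branch_drives(self.ctx, state, gate_stance, gate_swing, gamma, self.gains)
        out: dict[str, float] = {}
        for joint, (a, b) in JOINT_CHANNELS.items():
            pilo = self.pilocarpine.get(joint, (0.0, 0.0))
            oa, ob = self.pmns[joint].step((drives[a], drives[b]), tuple(pilo))
            out[a], out[b] = oa, ob
        return MotorOutput(**out)
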