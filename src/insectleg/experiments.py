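"""Scenario catalog and open-loop runner for the four experiment groups.

Eleven scenarios reproduce the reflex and oscillation experiments on a
single fixed leg: context-dependent reflex reversal under femur bending
(exp31_*), active reaction of the femur-tibia joint under slow fCO
elongation during straight (exp321_*) and curve walking (exp322_*), the
direction-independent levator response of the coxa-trochanterofemur
joint (exp33), and the pilocarpine-oscillation experiments with
superimposed rhythmic sensory input (exp341_*/exp342_*).

All runs are open loop: the leg is fixed, interleg coordination is cut,
motor outputs are recorded but never move the leg.  Everything is
deterministic - two runs of the same scenario produce identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import classify_reflex
from .config import DEFAULT_PILOCARPINE, GAINS
from .core import CompiledNetwork, SimClock
from .joints import LegContext, LegController
from .motivation import (
    SensoryEvent,
    build_motivation_net,
    events_to_port_series,
    initial_states,
    state_from_outputs,
)
from .stimuli import CsProtocol, FcoProtocol, generate_cs, generate_fco

__all__ = [
    "Scenario",
    "ExperimentResult",
    "build_catalog",
    "run_scenario",
    "run_catalog",
    "TRUTH_TABLE",
    "evaluate_truth_table",
]

TRACE_COLUMNS = [
    "time_s", "protractor", "retractor", "levator", "depressor", "flexor",
    "extensor", "cs_stimulus", "fco_pos", "fco_vel", "state_walk",
    "state_stand", "state_fw", "state_bw", "state_swing", "state_stance",
]


@dataclass(frozen=True)
class Scenario:
    """One open-loop experiment: leg, context, stimuli, duration."""

    id: str
    leg: LegContext
    direction: str = "FW"
    cs: CsProtocol | None = None
    fco: FcoProtocol | None = None
    pilocarpine: dict[str, tuple[float, float]] | None = None
    duration: float = 12.0
    tactile: tuple[SensoryEvent, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.direction.upper() not in ("FW", "BW"):
            raise ValueError("direction must be FW or BW")
        if self.id.startswith("exp34") and self.pilocarpine is None:
            raise ValueError("exp34x scenarios require a pilocarpine config")
        if not self.id.startswith("exp34") and self.pilocarpine is not None:
            raise ValueError("only exp34x scenarios carry pilocarpine")


@dataclass
class ExperimentResult:
    """Traces, events and the scenario that produced them."""

    traces: pd.DataFrame  # indexed by time, TRACE_COLUMNS[1:] as columns
    events: list[SensoryEvent]
    scenario: Scenario
    dt: float = 0.01

    @property
    def motivation_log(self) -> pd.DataFrame:
        return self.traces[[c for c in self.traces.columns if c.startswith("state_")]]


def build_catalog() -> dict[str, Scenario]:
    """The eleven standard scenarios."""
    middle = LegContext(leg_id="middle_left")
    front = LegContext(leg_id="front_left")
    fco6 = FcoProtocol(period=6.0, n_cycles=2)
    cat = [
        Scenario("exp31_fw", middle, "FW", cs=CsProtocol(n_cycles=2),
                 description="caudal CS bending, forward walking"),
        Scenario("exp31_bw", middle, "BW", cs=CsProtocol(n_cycles=2),
                 description="caudal CS bending, backward walking"),
        Scenario("exp321_fw", front, "FW", fco=fco6,
                 description="slow fCO elongation, forward walking"),
        Scenario("exp321_bw", front, "BW", fco=fco6,
                 description="slow fCO elongation, backward walking"),
        Scenario("exp322_inner", LegContext(leg_id="front_right", theta=75.0), "FW",
                 fco=fco6, description="curve walking (right turn), inner front leg"),
        Scenario("exp322_outer", LegContext(leg_id="front_left", theta=75.0), "FW",
                 fco=fco6, description="curve walking (right turn), outer front leg"),
        Scenario("exp33", middle, "FW", fco=fco6,
                 description="slow fCO elongation, levator/depressor response"),
        Scenario("exp341_short", middle, "FW",
                 cs=CsProtocol(period=3.6, n_cycles=10),
                 pilocarpine=dict(DEFAULT_PILOCARPINE), duration=36.0,
                 description="pilocarpine + CS rhythm faster than all intrinsic rhythms"),
        Scenario("exp341_long", middle, "FW",
                 cs=CsProtocol(period=10.8, n_cycles=3),
                 pilocarpine=dict(DEFAULT_PILOCARPINE), duration=36.0,
                 description="pilocarpine + CS rhythm slower than beta/gamma rhythms"),
        Scenario("exp342_short", middle, "FW",
                 fco=FcoProtocol(period=3.6, n_cycles=10),
                 pilocarpine=dict(DEFAULT_PILOCARPINE), duration=36.0,
                 description="pilocarpine + fCO rhythm faster than all intrinsic rhythms"),
        Scenario("exp342_long", middle, "FW",
                 fco=FcoProtocol(period=7.0, n_cycles=5),
                 pilocarpine=dict(DEFAULT_PILOCARPINE), duration=36.0,
                 description="pilocarpine + 7 s fCO rhythm (alpha still entrained)"),
    ]
    return {s.id: s for s in cat}


def run_scenario(scenario: Scenario, dt: float = 0.01,
                 duration: float | None = None,
                 calibration: dict | None = None,
                 gains: dict[str, float] | None = None) -> ExperimentResult:
    """Simulate one scenario open loop and return the full trace set.

    The motivation network and the three premotor nets advance on the
    same fixed-step clock; joint angles stay at the scenario's fixed
    values except that the femur-tibia angle used by the height
    controller follows the fCO apodeme position.
    """
    g = {**GAINS, **(gains or {})}
    clock = SimClock(dt=dt, duration=duration or scenario.duration)
    n = clock.n_steps
    cs_series = np.zeros(n)
    fco_pos = np.zeros(n)
    fco_vel = np.zeros(n)
    events: list[SensoryEvent] = list(scenario.tactile)
    if scenario.cs is not None:
        cs_series, cs_events = generate_cs(scenario.cs, clock)
        events += cs_events
    if scenario.fco is not None:
        fco_pos, fco_vel, fco_events = generate_fco(scenario.fco, clock)
        events += fco_events

    net = build_motivation_net(g)
    engine = CompiledNetwork(net, dt=dt)
    engine.reset(initial_states(scenario.direction, gains=g))
    port_series = events_to_port_series(events, clock)
    ports = list(port_series)
    port_idx = np.array([engine.port_index[p] for p in ports], dtype=int)
    port_mat = np.array([port_series[p] for p in ports]) if ports else None

    leg = LegController(scenario.leg, dt=dt, calibration=calibration,
                        pilocarpine=scenario.pilocarpine, gains=g)
    gi = {u: engine.index[u] for u in
          ("walk_e", "stand_e", "fw_e", "bw_e", "swing_e", "stance_e",
           "velocity", "gate_stance", "gate_swing", "gate_load")}

    rec = np.zeros((n, len(TRACE_COLUMNS) - 1))
    ext = np.zeros(engine.n)
    for k in range(n):
        if port_mat is not None:
            ext[:] = 0.0
            np.add.at(ext, port_idx, port_mat[:, k])
            out = engine.step(ext)
        else:
            out = engine.step()
        state = state_from_outputs({u: out[i] for u, i in gi.items()
                                    if not u.startswith("gate")})
        gate_st = out[gi["gate_stance"]] + out[gi["gate_load"]]
        gate_sw = out[gi["gate_swing"]]
        gamma_eff = scenario.leg.gamma_angle + g["fco_gamma_gain"] * fco_pos[k]
        motor = leg.step(state, gate_st, gate_sw, gamma_eff)
        rec[k, 0:6] = [motor.protractor, motor.retractor, motor.levator,
                       motor.depressor, motor.flexor, motor.extensor]
        rec[k, 6] = cs_series[k]
        rec[k, 7] = fco_pos[k]
        rec[k, 8] = fco_vel[k]
        rec[k, 9:15] = [state.walk_active, state.stand_active,
                        state.forward_active, state.backward_active,
                        state.swing_active, state.stance_active]
    traces = pd.DataFrame(rec, index=clock.times(), columns=TRACE_COLUMNS[1:])
    traces.index.name = "time_s"
    return ExperimentResult(traces=traces, events=events, scenario=scenario, dt=dt)


# Reflex truth table: the observation rows of the biological experiments,
# as (row label, scenario, joint, stimulus phase, acceptable dominant
# channels, whether a weak/neutral outcome is the expected one).
TRUTH_TABLE: list[tuple[str, str, str, str, tuple[str, ...], bool]] = [
    ("fw caudal bending -> retractor", "exp31_fw", "alpha", "stimulus", ("retractor",), False),
    ("fw caudal relaxation -> protractor", "exp31_fw", "alpha", "relax", ("protractor",), False),
    ("bw caudal bending -> protractor", "exp31_bw", "alpha", "stimulus", ("protractor",), False),
    ("fw fCO elongation -> flexor", "exp321_fw", "gamma", "stimulus", ("flexor",), False),
    ("bw fCO elongation -> extensor", "exp321_bw", "gamma", "stimulus", ("extensor",), False),
    ("inner leg fCO elongation -> flexor", "exp322_inner", "gamma", "stimulus", ("flexor",), False),
    ("outer leg fCO elongation -> weak extensor or neutral", "exp322_outer", "gamma",
     "stimulus", ("extensor", "none"), True),
    ("fw fCO elongation -> levator", "exp33", "beta", "stimulus", ("levator",), False),
    ("bw fCO elongation -> levator", "exp321_bw", "beta", "stimulus", ("levator",), False),
]


def evaluate_truth_table(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """Classify every truth-table row against the observation column."""
    rows = []
    for label, sid, joint, phase, accepted, weak_ok in TRUTH_TABLE:
        outcome = classify_reflex(results[sid], joint, phase)
        ok = outcome.dominant_channel in accepted
        if weak_ok:
            ok = ok and outcome.strength in ("weak", "neutral")
        else:
            ok = ok and outcome.strength in ("clear", "weak")
        rows.append({
            "row": label, "scenario": sid, "joint": joint, "phase": phase,
            "dominant": outcome.dominant_channel, "strength": outcome.strength,
            "dominance_ratio": round(outcome.dominance_ratio, 2), "pass": ok,
        })
    return pd.DataFrame(rows)


def run_catalog(ids: list[str] | None = None, out_dir=None,
                dt: float = 0.01) -> tuple[dict[str, ExperimentResult], pd.DataFrame]:
    """Run scenarios (default: all), optionally writing one trace per id.

    Returns the results plus a summary table; scenarios covered by the
    reflex truth table carry a pass/fail verdict.  A failing scenario is
    recorded and the run continues.
    """
    from .traceio import write_trace

    catalog = build_catalog()
    if ids is None:
        ids = list(catalog)
    unknown = [i for i in ids if i not in catalog]
    if unknown:
        raise ValueError(f"unknown scenario ids {unknown}; available: {sorted(catalog)}")
    results: dict[str, ExperimentResult] = {}
    rows = []
    for sid in ids:
        try:
            res = run_scenario(catalog[sid], dt=dt)
        except Exception as exc:  # record and continue per catalog contract
            rows.append({"scenario": sid, "status": f"error: {exc}"})
            continue
        results[sid] = res
        if out_dir is not None:
            write_trace(res, f"{out_dir}/{sid}.csv")
        rows.append({"scenario": sid, "status": "ok",
                     "description": catalog[sid].description})
    summary = pd.DataFrame(rows)
    needed = {sid for _, sid, *_ in TRUTH_TABLE}
    checked = evaluate_truth_table(results) if needed <= results.keys() else None
    if checked is not None:
        verdict = checked.groupby("scenario")["pass"].all()
        summary = summary.merge(verdict.rename("truth_table_pass"),
                                left_on="scenario", right_index=True, how="left")
    return results, summary
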