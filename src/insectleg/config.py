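"""Default parameters, calibration constants and run configuration.

All activations are in millivolts, times in seconds, fCO apodeme
positions in millimetres and joint angles in degrees.  The premotor
calibration constants below were fitted once with
:func:`insectleg.calibrate.calibrate_all` so that the default
pilocarpine injections reproduce the target half-phase durations and
periods of the three joint rhythms; they are frozen here and versioned
with the package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "GAINS",
    "PMN_CALIBRATION",
    "DEFAULT_PILOCARPINE",
    "PMN_TARGETS",
    "RunConfig",
    "calibration_hash",
]

# Network-level gains (see docs/methods.md for rationale).
GAINS: dict[str, float] = {
    # motivation layer
    "tonic_drive": 20.0,        # mV, output of the tonic drive unit
    "walk_recurrence": 0.25,    # Walk -> monopole excitatory units (5 mV drive)
    "monopole_cross_inhibition": 2.0,
    "gate_weight": 1.0,         # turquoise gate -> Swing/Stance (stimulus 10 mV = 2x drive)
    "stimulus_amplitude": 10.0, # mV, default sensory event magnitude
    "velocity_inhibition": 2.0, # Stand -> velocity (full suppression)
    # stance / swing branch amplitudes at full velocity command (20 mV)
    "stance_alpha_amp": 15.0,
    "stance_gamma_amp": 15.0,
    "curve_weak_amp": 3.0,      # outer-leg weak drive during curve walking
    "swing_amp": 10.0,
    "stance_support": 15.0,     # depressor-ward bias of the beta drive during stance
    "swing_lift": 10.0,         # levator-ward bias of the beta drive during swing
    # height controller
    "height_gain": 1.0,         # mV per degree of gamma deviation
    "height_reference_deg": 60.0,
    "fco_gamma_gain": 100.0,    # degrees of gamma flexion per mm of apodeme elongation
    # unit dynamics
    "tau_lp": 0.05,             # s, default low-pass time constant
    "pmn_g_ei": 1.0,            # excitatory -> phasic-inhibitory gain in the premotor net
}

# fCO ramp-velocity gates (mm/s): at or below the slow gate the ramp is
# routed to the assistance (active-reaction) pathway; strictly above the
# fast gate it is tagged resistance; in between nothing is routed.
FCO_SLOW_GATE = 2.0
FCO_FAST_GATE = 6.0

# Default constant injection emulating pilocarpine, per joint and branch
# (agonist, antagonist) = (protractor, retractor), (levator, depressor),
# (flexor, extensor), in mV.
DEFAULT_PILOCARPINE: dict[str, tuple[float, float]] = {
    "alpha": (3.0, 6.0),
    "beta": (13.0, 3.0),
    "gamma": (5.0, 5.0),
}

# Calibration targets: (half_phase_a, half_phase_b, period) in seconds for
# the default injections above.
PMN_TARGETS: dict[str, tuple[float, float, float]] = {
    "alpha": (3.7, 6.7, 10.2),
    "beta": (2.8, 1.8, 4.6),
    "gamma": (2.1, 2.1, 4.2),
}

# Frozen premotor-net constants: per-joint high-pass time constant of the
# phasic inhibitory units, the two lateral-inhibition gains
# (w_ab: I_a -> E_b, w_ba: I_b -> E_a) and the crossed
# premotor-to-motoneuron suppression gain.  Values produced by
# `insectleg calibrate` at dt = 0.01 s.
PMN_CALIBRATION: dict[str, dict[str, float]] = {
    "alpha": {"tau_hp": 2.7439, "w_ab": 5.163, "w_ba": 6.668, "mn_cross": 0.5},
    "beta": {"tau_hp": 1.4901, "w_ab": 1.248, "w_ba": 13.299, "mn_cross": 0.8},
    "gamma": {"tau_hp": 1.3572, "w_ab": 3.802, "w_ba": 3.802, "mn_cross": 0.5},
}


def calibration_hash(calibration: dict | None = None) -> str:
    """Short stable hash of the calibration block, recorded in trace headers."""
    payload = json.dumps(calibration or PMN_CALIBRATION, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Validated configuration for scenario runs."""

    scenario_ids: list[str] = field(default_factory=list)
    dt: float = 0.01
    duration: float | None = None  # None = scenario default
    pilocarpine: dict[str, tuple[float, float]] | None = None
    calibration: dict[str, dict[str, float]] = field(
        default_factory=lambda: {j: dict(v) for j, v in PMN_CALIBRATION.items()}
    )
    gains: dict[str, float] = field(default_factory=lambda: dict(GAINS))
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be > 0")
        for joint in ("alpha", "beta", "gamma"):
            if joint not in self.calibration:
                raise ValueError(f"calibration missing joint {joint!r}")

    def validate_scenarios(self, catalog: dict) -> None:
        unknown = [s for s in self.scenario_ids if s not in catalog]
        if unknown:
            raise ValueError(
                f"unknown scenario ids {unknown}; available: {sorted(catalog)}"
            )

    def to_json(self) -> str:
        d = asdict(self)
        d["pilocarpine"] = (
            {k: list(v) for k, v in self.pilocarpine.items()}
            if self.pilocarpine
            else None
        )
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("pilocarpine"):
            d["pilocarpine"] = {k: tuple(v) for k, v in d["pilocarpine"].items()}
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())
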