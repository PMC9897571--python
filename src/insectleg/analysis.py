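"""Derived statistics: periods, half-phases, reflex classification,
entrainment and phase-reset detection.

Oscillation measurements use a simple onset-threshold method suited to
the clamped piecewise-linear unit outputs: onsets are upward crossings
of a threshold at a fixed fraction (default 50%) of the channel's
maximum; the period is the mean inter-onset interval and the half-phase
the mean above-threshold duration per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeriodEstimate",
    "ReflexOutcome",
    "ResetFlag",
    "estimate_period",
    "classify_reflex",
    "detect_reset",
    "entrainment_check",
]

# Mean activation below which a channel counts as silent (mV), and the
# dominance ratio separating a clear from a weak reflex outcome.
NEUTRAL_EPS = 0.5
CLEAR_RATIO = 2.0
WEAK_LEVEL = 5.0


@dataclass(frozen=True)
class PeriodEstimate:
    """Onset-threshold oscillation measurement for one channel."""

    channel: str
    period_mean: float
    period_sd: float
    half_phase_a: float  # mean above-threshold duration per cycle
    half_phase_b: float  # remainder of the period
    n_cycles: int
    method: str = "onset-threshold@0.5max"

    @property
    def oscillating(self) -> bool:
        return self.n_cycles >= 2 and np.isfinite(self.period_mean)


@dataclass(frozen=True)
class ReflexOutcome:
    """Dominant antagonist of a joint during one stimulus phase."""

    joint: str
    stimulus_phase: str
    dominant_channel: str
    dominance_ratio: float
    strength: str  # 'clear' | 'weak' | 'neutral'
    mean_dominant: float = 0.0
    mean_other: float = 0.0


@dataclass(frozen=True)
class ResetFlag:
    """Per-transition phase-reset verdict."""

    transition_time: float
    onset_latency: float
    reset: bool


def _onsets(y: np.ndarray, dt: float, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    above = y >= threshold
    on = np.flatnonzero(~above[:-1] & above[1:]) + 1
    off = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    return on, off


def estimate_period(trace: pd.DataFrame, channel: str,
                    threshold_fraction: float = 0.5,
                    skip: float = 0.0) -> PeriodEstimate:
    """Measure period and half-phase of one channel by threshold onsets.

    ``skip`` seconds are discarded from the start to remove the startup
    transient.  Fewer than two onsets yield a "no oscillation" result
    (NaN period, ``oscillating`` False) rather than an exception.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    t = np.asarray(trace.index, dtype=float)
    dt = float(t[1] - t[0])
    y = np.asarray(trace[channel], dtype=float)
    i0 = int(np.searchsorted(t, t[0] + skip))
    y = y[i0:]
    peak = y.max() if y.size else 0.0
    if peak <= 0:
        return PeriodEstimate(channel, np.nan, np.nan, np.nan, np.nan, 0)
    thr = threshold_fraction * peak
    on, off = _onsets(y, dt, thr)
    if len(on) < 2:
        return PeriodEstimate(channel, np.nan, np.nan, np.nan, np.nan, max(len(on) - 1, 0))
    intervals = np.diff(on) * dt
    durations = []
    for o in on[:-1]:
        later = off[off > o]
        if later.size:
            durations.append((later[0] - o) * dt)
    half_a = float(np.mean(durations)) if durations else np.nan
    period = float(np.mean(intervals))
    return PeriodEstimate(
        channel=channel,
        period_mean=period,
        period_sd=float(np.std(intervals)),
        half_phase_a=half_a,
        half_phase_b=period - half_a if np.isfinite(half_a) else np.nan,
        n_cycles=len(on) - 1,
    )


def _phase_windows(events, kinds: tuple[str, ...]) -> list[tuple[float, float]]:
    return [(ev.onset, ev.offset) for ev in events if ev.kind in kinds]


STIMULUS_KINDS = {
    "stimulus": ("cs_caudal_bend", "cs_rostral_bend", "fco_elongation_ramp"),
    "relax": ("cs_caudal_relax", "cs_rostral_relax", "fco_shortening_ramp"),
}


def classify_reflex(result, joint: str, phase: str = "stimulus") -> ReflexOutcome:
    """Classify the dominant antagonist of ``joint`` during a stimulus phase.

    The dominant channel is the antagonist with the larger mean motor
    activation across all windows of the chosen phase ('stimulus' =
    bending/elongation, 'relax' = relaxation/shortening).  The outcome
    is 'neutral' when both channels are essentially silent or tied,
    'weak' when dominance is marginal or the winner's activation small,
    'clear' otherwise.
    """
    from .joints import JOINT_CHANNELS

    a, b = JOINT_CHANNELS[joint]
    windows = _phase_windows(result.events, STIMULUS_KINDS[phase])
    if not windows:
        raise ValueError(f"no {phase!r} windows among the scenario events")
    t = np.asarray(result.traces.index, dtype=float)
    mask = np.zeros(len(t), dtype=bool)
    for t0, t1 in windows:
        mask |= (t > t0) & (t <= t1)
    mean_a = float(result.traces[a].to_numpy()[mask].mean())
    mean_b = float(result.traces[b].to_numpy()[mask].mean())
    strong, weakv = (mean_a, mean_b) if mean_a >= mean_b else (mean_b, mean_a)
    dominant = a if mean_a >= mean_b else b
    ratio = strong / max(weakv, NEUTRAL_EPS)
    if strong < NEUTRAL_EPS or abs(mean_a - mean_b) < NEUTRAL_EPS:
        strength, dominant = "neutral", "none"
    elif ratio < CLEAR_RATIO or strong < WEAK_LEVEL:
        strength = "weak"
    else:
        strength = "clear"
    return ReflexOutcome(joint, phase, dominant, max(ratio, 1.0), strength,
                         mean_dominant=strong, mean_other=weakv)


def detect_reset(trace: pd.DataFrame, channel: str,
                 transition_times: list[float], intrinsic_period: float,
                 threshold_fraction: float = 0.5) -> list[ResetFlag]:
    """Decide whether stimulus transitions reset the channel's rhythm.

    For each transition the latency to the next channel onset is
    measured; the rhythm counts as reset when these latencies are fixed
    across transitions (standard deviation below 10% of the intrinsic
    period) instead of drifting with the free-running phase.  With no
    oscillation or fewer than two usable transitions the result is
    empty.
    """
    t = np.asarray(trace.index, dtype=float)
    dt = float(t[1] - t[0])
    y = np.asarray(trace[channel], dtype=float)
    peak = y.max()
    if peak <= 0:
        return []
    on, _ = _onsets(y, dt, threshold_fraction * peak)
    if len(on) < 2:
        return []
    onset_times = t[on]
    latencies = []
    usable = []
    for tt in transition_times:
        later = onset_times[onset_times > tt]
        if later.size:
            usable.append(tt)
            latencies.append(float(later[0] - tt))
    if len(latencies) < 2:
        return []
    is_reset = bool(np.std(latencies) < 0.1 * intrinsic_period)
    return [ResetFlag(tt, lat, is_reset) for tt, lat in zip(usable, latencies)]


def entrainment_check(trace: pd.DataFrame, channel: str, stimulus_period: float,
                      skip: float = 0.0, tolerance: float = 0.05
                      ) -> tuple[bool, float]:
    """Is the channel's rhythm locked to the stimulus period (within 5%)?"""
    est = estimate_period(trace, channel, skip=skip)
    if not est.oscillating:
        return False, est.period_mean
    locked = abs(est.period_mean - stimulus_period) / stimulus_period < tolerance
    return locked, est.period_mean
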