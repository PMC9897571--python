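"""Fitting the premotor-net constants to the target joint rhythms.

The premotor relaxation oscillator has, per joint, three free constants
the source experiments do not pin down: the high-pass time constant of
the phasic inhibitory units and the two lateral-inhibition gains.  They
are fitted here - once - so that the default pilocarpine injections
reproduce the target half-phase durations and periods, then frozen in
:mod:`insectleg.config`.

The fit exploits the oscillator's structure: to first order a branch's
ON duration is ``tau_hp * log(w * drive_own / drive_other)``, so the
total rhythm scales with ``tau_hp`` while each lateral gain mainly
controls its own branch's half-phase.  A damped fixed-point iteration
on (tau_hp, log w_ab, log w_ba) converges in a few tens of simulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import estimate_period
from .config import DEFAULT_PILOCARPINE, PMN_TARGETS
from .joints import JOINT_CHANNELS, PmnNet, PmnSimulator

__all__ = ["MN_CROSS", "measure_pmn", "fit_pmn", "calibrate_all"]

# Crossed premotor->motoneuron suppression per joint.  The beta joint's
# strongly asymmetric drives (13/3 mV) need a higher crossing gain to keep
# antagonist co-activation within the soft-WTA bound; the cost - a slightly
# longer switching gap - is absorbed by the balanced fit below.
MN_CROSS = {"alpha": 0.5, "beta": 0.8, "gamma": 0.5}


def measure_pmn(joint: str, params: dict[str, float],
                drives: tuple[float, float], duration: float = 90.0,
                dt: float = 0.01, skip: float = 15.0
                ) -> tuple[float, float, float]:
    """Simulate one premotor net under constant injection and measure
    (half_phase_a, half_phase_b, period); NaNs when it does not cycle."""
    net = PmnNet(joint=joint, hp_time_constant=params["tau_hp"],
                 w_ab=params["w_ab"], w_ba=params["w_ba"],
                 mn_cross=params.get("mn_cross", MN_CROSS[joint]))
    sim = PmnSimulator(net, dt=dt)
    rec = sim.run(duration, pilocarpine=drives)
    a, b = JOINT_CHANNELS[joint]
    trace = pd.DataFrame(rec, index=(np.arange(len(rec)) + 1) * dt, columns=[a, b])
    est_a = estimate_period(trace, a, skip=skip)
    est_b = estimate_period(trace, b, skip=skip)
    if not (est_a.oscillating and est_b.oscillating):
        return np.nan, np.nan, np.nan
    return est_a.half_phase_a, est_b.half_phase_a, 0.5 * (est_a.period_mean + est_b.period_mean)


def _fit_half_phases(joint, drives, Ha, Hb, tau, wab, wba, iters, damping, dt):
    """Inner loop: match the two half-phase targets."""
    for _ in range(iters):
        ha, hb, _per = measure_pmn(joint, {"tau_hp": tau, "w_ab": wab, "w_ba": wba},
                                   drives, dt=dt)
        if not np.isfinite(ha):
            wab *= 1.5
            wba *= 1.5
            continue
        tau *= (Ha + Hb) / (ha + hb)
        wab *= float(np.exp(damping * (Ha - ha) / tau))
        wba *= float(np.exp(damping * (Hb - hb) / tau))
        wab = float(np.clip(wab, 1.2, 5000.0))
        wba = float(np.clip(wba, 1.2, 5000.0))
    return tau, wab, wba


def fit_pmn(joint: str, drives: tuple[float, float],
            targets: tuple[float, float, float],
            tau0: float = 1.5, w0: float = 5.0,
            iters: int = 25, damping: float = 0.8,
            dt: float = 0.01) -> dict[str, float]:
    """Fit (tau_hp, w_ab, w_ba) to ``targets`` = (half_a, half_b, period).

    With strictly one-sided motor outputs the inter-onset period exceeds
    the half-phase sum by the two switching gaps, so all three targets
    cannot be hit exactly when the printed half-phases already sum to
    (or beyond) the printed period.  The fit therefore balances the
    excess: half-phases are first matched exactly, the resulting gap is
    measured, and the three residuals are equalized by shaving a third
    of the excess off each half-phase target.
    """
    Ha, Hb, P = targets
    tau, wab, wba = _fit_half_phases(joint, drives, Ha, Hb, tau0, w0, w0,
                                     iters, damping, dt)
    ha, hb, per = measure_pmn(joint, {"tau_hp": tau, "w_ab": wab, "w_ba": wba},
                              drives, dt=dt)
    gap = per - ha - hb
    excess = (Ha + Hb + gap) - P
    if excess > 0:
        tau, wab, wba = _fit_half_phases(joint, drives, Ha - excess / 3,
                                         Hb - excess / 3, tau, wab, wba,
                                         iters, damping, dt)
    if drives[0] == drives[1]:
        # symmetric drives: enforce an exactly symmetric net
        wab = wba = 0.5 * (wab + wba)
    return {"tau_hp": round(tau, 4), "w_ab": round(wab, 3),
            "w_ba": round(wba, 3), "mn_cross": MN_CROSS[joint]}


def calibrate_all(dt: float = 0.01, iters: int = 25) -> dict[str, dict[str, float]]:
    """Fit all three joints to their targets under the default injections."""
    out = {}
    for joint in JOINT_CHANNELS:
        out[joint] = fit_pmn(joint, DEFAULT_PILOCARPINE[joint],
                             PMN_TARGETS[joint], iters=iters, dt=dt)
    return out
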