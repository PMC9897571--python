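"""Trace persistence: CSV files with a fixed channel layout.

Every trace file carries comment lines (prefixed ``#``) recording the
step size, scenario id and a hash of the premotor calibration, followed
by one row per simulation step with six significant digits.  Reruns of
the same scenario produce byte-identical files.
"""

from __future__ import annotations

import pandas as pd

from .config import calibration_hash
from .experiments import TRACE_COLUMNS, ExperimentResult

__all__ = ["write_trace", "read_trace"]


def write_trace(result: ExperimentResult, path,
                calibration: dict | None = None) -> None:
    """Write an experiment's traces to ``path`` as commented CSV."""
    df = result.traces.reset_index()
    df.columns = TRACE_COLUMNS
    try:
        with open(path, "w", newline="") as fh:
            fh.write(f"# scenario: {result.scenario.id}\n")
            fh.write(f"# dt: {result.dt}\n")
            fh.write(f"# calibration: {calibration_hash(calibration)}\n")
            df.to_csv(fh, index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"cannot write trace to {path}: {exc}") from exc


def read_trace(path) -> pd.DataFrame:
    """Read a trace file back, indexed by time."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace {path} is missing columns {missing}")
    return df.set_index("time_s")
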