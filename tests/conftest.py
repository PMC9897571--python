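import numpy as np
import pandas as pd
import pytest

from insectleg.analysis import estimate_period
from insectleg.config import DEFAULT_PILOCARPINE
from insectleg.experiments import build_catalog, run_catalog
from insectleg.joints import JOINT_CHANNELS, PmnNet, PmnSimulator


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def catalog_results():
    """All eleven scenarios, run once for the whole session."""
    results, summary = run_catalog()
    assert (summary["status"] == "ok").all()
    return results


def run_pure_pilocarpine(joint: str, duration: float = 60.0, dt: float = 0.01,
                         pilocarpine: tuple[float, float] | None = None) -> pd.DataFrame:
    """Premotor net under constant injection only; returns a 2-column trace."""
    sim = PmnSimulator(PmnNet.from_calibration(joint), dt=dt)
    rec = sim.run(duration, pilocarpine=pilocarpine or DEFAULT_PILOCARPINE[joint])
    a, b = JOINT_CHANNELS[joint]
    return pd.DataFrame(rec, index=(np.arange(len(rec)) + 1) * dt, columns=[a, b])


@pytest.fixture(scope="session")
def pure_pilocarpine_traces():
    return {joint: run_pure_pilocarpine(joint) for joint in JOINT_CHANNELS}


def measure_rhythm(trace: pd.DataFrame, channel: str, skip: float = 15.0):
    return estimate_period(trace, channel, skip=skip)
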