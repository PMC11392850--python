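import datetime as dt

import numpy as np
import pytest

from rempropensity.hypnogram import Hypnogram, State, label_phase

CODE = {"W": State.WAKE.value, "N": State.NREM.value, "R": State.REM.value}


def hypnogram_from_string(
    s: str,
    epoch_s: float = 2.5,
    start_clock: dt.time = dt.time(7, 0, 0),
    recording_id: str = "test",
    labelled: bool = True,
) -> Hypnogram:
    """Build a hypnogram from a compact state string like 'RRNNWNR'."""
    states = np.array([CODE[ch] for ch in s], dtype=np.int8)
    h = Hypnogram(
        states=states,
        epoch_s=epoch_s,
        start_clock=start_clock,
        recording_id=recording_id,
    )
    return label_phase(h) if labelled else h


@pytest.fixture
def make_hypnogram():
    return hypnogram_from_string
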