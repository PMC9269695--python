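import numpy as np
import pandas as pd
import pytest

from actisleep import AlignedNight, CountEpochSeries, Hypnogram
from actisleep.types import minute_range

START = pd.Timestamp("2024-03-01 23:00:00")


def states_from_string(s: str) -> np.ndarray:
    """'S'/'W' string -> boolean sleep array (True = Sleep)."""
    return np.array([c == "S" for c in s.replace(" ", "")])


def make_aligned(
    psg: str,
    ag: str = None,
    included: str = None,
    pid: str = "p01",
    lights_out=START,
) -> AlignedNight:
    """Build an AlignedNight from 'SW' strings, TIB from lights-out to
    the last included PSG Sleep minute."""
    psg_sleep = states_from_string(psg)
    ag_sleep = states_from_string(ag) if ag is not None else psg_sleep.copy()
    n = len(psg_sleep)
    inc = (
        np.array([c == "1" for c in included.replace(" ", "")])
        if included is not None
        else np.ones(n, dtype=bool)
    )
    idx = minute_range(START, n)
    tib_start = int(np.searchsorted(idx.asi8, pd.Timestamp(lights_out).value))
    anchors = np.nonzero(psg_sleep & inc)[0]
    anchors = anchors[anchors >= tib_start]
    return AlignedNight(
        participant_id=pid,
        minute_start=idx,
        psg_sleep=psg_sleep,
        ag_sleep=ag_sleep,
        included=inc,
        tib_start_idx=tib_start,
        tib_end_idx=int(anchors[-1]),
    )


def make_counts(counts, epoch_len_s=60, pid="p01", start=START) -> CountEpochSeries:
    counts = np.asarray(counts)
    freq = f"{epoch_len_s}s"
    return CountEpochSeries(
        participant_id=pid,
        epoch_start=pd.date_range(start, periods=len(counts), freq=freq),
        counts=counts,
        epoch_len_s=epoch_len_s,
    )


def make_hypnogram(stages, scorable=None, pid="p01", start=START, lights_out=None):
    stages = np.asarray(stages, dtype=object)
    scorable = (
        np.ones(len(stages), dtype=bool) if scorable is None else np.asarray(scorable)
    )
    return Hypnogram(
        participant_id=pid,
        epoch_start=pd.date_range(start, periods=len(stages), freq="30s"),
        stage=stages,
        scorable=scorable,
        lights_out=lights_out if lights_out is not None else start,
    )


@pytest.fixture
def toy_night() -> AlignedNight:
    """The 10-minute reference night: W W S W S S S S S S."""
    return make_aligned("WWSWSSSSSS")
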