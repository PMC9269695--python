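"""Core containers for paired actigraphy / polysomnography nights.

All epoch and minute timestamps label the *start* of their interval;
intervals are half-open ``[t, t + length)``.  Binary sleep/wake state is
represented as a boolean array with ``True`` = Sleep, ``False`` = Wake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SLEEP = True
WAKE = False

#: AASM stage labels accepted in hypnogram files and their binary collapse.
STAGE_TO_BINARY = {
    "W": "Wake",
    "N1": "Sleep",
    "N2": "Sleep",
    "N3": "Sleep",
    "REM": "Sleep",
    "Wake": "Wake",
    "Sleep": "Sleep",
}


class SleepDataError(ValueError):
    """Invalid or inconsistent input data."""


class GapError(SleepDataError):
    """Non-uniform epoch spacing (a missing device epoch is an error)."""


class NoSleepError(SleepDataError):
    """A night with no scorable PSG sleep after lights-out."""


def _as_datetime_index(ts) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(ts)
    if idx.hasnans:
        raise SleepDataError("timestamps contain NaT")
    return idx


def _check_uniform_spacing(idx: pd.DatetimeIndex, step_s: float, what: str) -> None:
    if len(idx) < 2:
        return
    diffs = np.diff(idx.asi8) / 1e9
    bad = np.nonzero(diffs != step_s)[0]
    if bad.size:
        i = int(bad[0])
        raise GapError(
            f"{what}: expected {step_s:g} s spacing but found a "
            f"{diffs[i]:g} s step after {idx[i]}"
        )


@dataclass
class CountEpochSeries:
    """Activity-count epochs from the wrist device (x-axis counts).

    Parameters
    ----------
    participant_id : str
    epoch_start : pandas.DatetimeIndex
        Uniformly spaced epoch start times.
    counts : numpy.ndarray
        Non-negative integer activity counts, one per epoch.
    epoch_len_s : int
        Epoch length in seconds (typically 1 or 60).
    """

    participant_id: str
    epoch_start: pd.DatetimeIndex
    counts: np.ndarray
    epoch_len_s: int

    def __post_init__(self) -> None:
        self.epoch_start = _as_datetime_index(self.epoch_start)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != len(self.epoch_start):
            raise SleepDataError("counts and epoch_start must have equal length")
        if len(self.counts) and np.any(self.counts < 0):
            i = int(np.argmax(self.counts < 0))
            raise SleepDataError(
                f"negative activity count {self.counts[i]} at {self.epoch_start[i]}"
            )
        if self.epoch_len_s <= 0:
            raise SleepDataError("epoch_len_s must be positive")
        _check_uniform_spacing(self.epoch_start, self.epoch_len_s, "count series")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class Hypnogram:
    """PSG hypnogram: 30 s staged epochs plus the lights-out event.

    ``stage`` holds AASM labels (W/N1/N2/N3/REM) or the binary labels
    Wake/Sleep; ``scorable`` flags epochs a technician could score.
    """

    participant_id: str
    epoch_start: pd.DatetimeIndex
    stage: np.ndarray
    scorable: np.ndarray
    lights_out: pd.Timestamp
    epoch_len_s: int = 30

    def __post_init__(self) -> None:
        self.epoch_start = _as_datetime_index(self.epoch_start)
        self.stage = np.asarray(self.stage, dtype=object)
        self.scorable = np.asarray(self.scorable, dtype=bool)
        if not (len(self.stage) == len(self.scorable) == len(self.epoch_start)):
            raise SleepDataError("stage, scorable and epoch_start lengths differ")
        _check_uniform_spacing(self.epoch_start, self.epoch_len_s, "hypnogram")
        for i, lab in enumerate(self.stage):
            if lab not in STAGE_TO_BINARY:
                raise SleepDataError(
                    f"unknown stage label {lab!r} at epoch {i} ({self.epoch_start[i]})"
                )
        self.lights_out = pd.Timestamp(self.lights_out)
        if len(self.epoch_start) and self.lights_out > self.epoch_start[-1]:
            raise SleepDataError("lights_out falls after the last hypnogram epoch")

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.stage, ("Wake", "Sleep")).all())

    def __len__(self) -> int:
        return len(self.stage)


@dataclass
class MinuteStates:
    """Minute-resolution binary sleep/wake states with scorable flags."""

    participant_id: str
    minute_start: pd.DatetimeIndex
    sleep: np.ndarray  # True = Sleep
    scorable: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start = _as_datetime_index(self.minute_start)
        self.sleep = np.asarray(self.sleep, dtype=bool)
        self.scorable = np.asarray(self.scorable, dtype=bool)
        if not (len(self.sleep) == len(self.scorable) == len(self.minute_start)):
            raise SleepDataError("sleep, scorable and minute_start lengths differ")
        _check_uniform_spacing(self.minute_start, 60, "minute states")

    def __len__(self) -> int:
        return len(self.sleep)


@dataclass
class AlignedNight:
    """Paired minute-level PSG and actigraph states within one night.

    ``included`` is False where the PSG minute was unscorable; excluded
    minutes are dropped from both streams in every downstream statistic.
    Time in Bed (TIB) spans ``tib_start_idx .. tib_end_idx`` inclusive,
    where the end index is the Awake anchor: the last included PSG minute
    scored Sleep.
    """

    participant_id: str
    minute_start: pd.DatetimeIndex
    psg_sleep: np.ndarray
    ag_sleep: np.ndarray
    included: np.ndarray
    tib_start_idx: int
    tib_end_idx: int

    def __post_init__(self) -> None:
        self.minute_start = _as_datetime_index(self.minute_start)
        self.psg_sleep = np.asarray(self.psg_sleep, dtype=bool)
        self.ag_sleep = np.asarray(self.ag_sleep, dtype=bool)
        self.included = np.asarray(self.included, dtype=bool)
        n = len(self.minute_start)
        if not (len(self.psg_sleep) == len(self.ag_sleep) == len(self.included) == n):
            raise SleepDataError("aligned arrays must share one length")
        _check_uniform_spacing(self.minute_start, 60, "aligned night")
        if not 0 <= self.tib_start_idx <= self.tib_end_idx < n:
            raise SleepDataError("TIB indices out of order or out of range")
        if not (self.psg_sleep[self.tib_end_idx] and self.included[self.tib_end_idx]):
            raise SleepDataError("TIB must end on an included PSG Sleep minute")

    def __len__(self) -> int:
        return len(self.minute_start)

    @property
    def tib_slice(self) -> slice:
        return slice(self.tib_start_idx, self.tib_end_idx + 1)

    @property
    def tib_min(self) -> int:
        """Included minutes within Time in Bed."""
        return int(self.included[self.tib_slice].sum())


@dataclass
class SleepMetrics:
    """The five sleep measures for one night, device and onset rule.

    ``se_asleep_pct`` is None when undefined (no onset detected).
    ``pre_onset_sleep_min`` counts isolated Sleep minutes before onset
    under multi-minute rules; it belongs to no named measure but closes
    the accounting identity SOL + TST + WASO + pre-onset sleep = TIB.
    """

    tib_min: int
    onset_idx: Optional[int]
    sol_min: int
    tst_min: int
    waso_min: int
    se_pct: float
    se_asleep_pct: Optional[float]
    pre_onset_sleep_min: int

    def as_dict(self) -> dict:
        return {
            "TST": float(self.tst_min),
            "SOL": float(self.sol_min),
            "WASO": float(self.waso_min),
            "SE": float(self.se_pct),
            "SE_ASLEEP": (
                float(self.se_asleep_pct) if self.se_asleep_pct is not None else np.nan
            ),
        }


def minute_range(start, n: int) -> pd.DatetimeIndex:
    """n consecutive minute-start timestamps beginning at ``start``."""
    return pd.date_range(pd.Timestamp(start), periods=n, freq="60s")
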