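"""Reading, collapsing and temporally aligning count and hypnogram data.

The file formats are plain CSV:

* counts:    ``participant_id, epoch_start (ISO-8601), axis_x`` (optional
  ``axis_y``/``axis_z`` columns are ignored — scoring uses the x axis only)
* hypnogram: ``participant_id, epoch_start, stage, scorable``
* events:    ``participant_id, lights_out``
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    STAGE_TO_BINARY,
    AlignedNight,
    CountEpochSeries,
    GapError,
    Hypnogram,
    MinuteStates,
    NoSleepError,
    SleepDataError,
)

DEFAULT_COUNT_SCHEMA = {
    "participant": "participant_id",
    "timestamp": "epoch_start",
    "counts": "axis_x",
}


def read_count_epochs_frame(
    df: pd.DataFrame,
    schema: Optional[Mapping[str, str]] = None,
    epoch_len_s: Optional[int] = None,
) -> CountEpochSeries:
    """Build a validated :class:`CountEpochSeries` from a counts frame."""
    cols = dict(DEFAULT_COUNT_SCHEMA)
    if schema:
        cols.update(schema)
    for key in ("timestamp", "counts"):
        if cols[key] not in df.columns:
            raise SleepDataError(f"missing column {cols[key]!r}")
    ts = pd.DatetimeIndex(pd.to_datetime(df[cols["timestamp"]]))
    pid = str(df[cols["participant"]].iloc[0]) if cols["participant"] in df.columns else ""
    if epoch_len_s is None:
        if len(ts) < 2:
            raise SleepDataError("cannot infer epoch length from a single row")
        epoch_len_s = int(np.diff(ts.asi8[:2])[0] / 1e9)
    return CountEpochSeries(
        participant_id=pid,
        epoch_start=ts,
        counts=df[cols["counts"]].to_numpy(),
        epoch_len_s=epoch_len_s,
    )


def read_count_epochs(
    path,
    schema: Optional[Mapping[str, str]] = None,
    epoch_len_s: Optional[int] = None,
) -> CountEpochSeries:
    """Read an activity-count CSV into a validated :class:`CountEpochSeries`.

    The epoch length is inferred from the timestamp spacing unless given.
    Non-uniform spacing raises :class:`GapError` naming the first gap;
    negative counts raise :class:`SleepDataError`.
    """
    return read_count_epochs_frame(pd.read_csv(path), schema, epoch_len_s)


def write_count_epochs(series: CountEpochSeries, path) -> None:
    pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "epoch_start": series.epoch_start.strftime("%Y-%m-%dT%H:%M:%S"),
            "axis_x": series.counts,
        }
    ).to_csv(path, index=False)


def read_hypnogram_frame(df: pd.DataFrame, lights_out=None) -> Hypnogram:
    """Build a validated :class:`Hypnogram` from a staged-epoch frame."""
    for col in ("epoch_start", "stage"):
        if col not in df.columns:
            raise SleepDataError(f"missing column {col!r}")
    ts = pd.DatetimeIndex(pd.to_datetime(df["epoch_start"]))
    pid = str(df["participant_id"].iloc[0]) if "participant_id" in df.columns else ""
    scorable = (
        df["scorable"].astype(int).to_numpy().astype(bool)
        if "scorable" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    if lights_out is None:
        lights_out = ts[0]
    return Hypnogram(
        participant_id=pid,
        epoch_start=ts,
        stage=df["stage"].to_numpy(),
        scorable=scorable,
        lights_out=pd.Timestamp(lights_out),
    )


def read_hypnogram(path, lights_out=None) -> Hypnogram:
    """Read a hypnogram CSV; ``lights_out`` may come from an events file."""
    return read_hypnogram_frame(pd.read_csv(path), lights_out)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {
            "participant_id": hyp.participant_id,
            "epoch_start": hyp.epoch_start.strftime("%Y-%m-%dT%H:%M:%S"),
            "stage": hyp.stage,
            "scorable": hyp.scorable.astype(int),
        }
    ).to_csv(path, index=False)


def read_events(path) -> dict:
    """Events CSV -> mapping participant_id -> lights_out timestamp."""
    df = pd.read_csv(path)
    return {
        str(r.participant_id): pd.Timestamp(r.lights_out)
        for r in df.itertuples(index=False)
    }


def collapse_epochs(series: CountEpochSeries, target_len_s: int = 60) -> CountEpochSeries:
    """Sum consecutive epochs into longer windows (e.g. 1 s -> 60 s).

    A trailing partial window is dropped with a warning.  Total counts
    over retained windows are conserved.
    """
    if target_len_s < series.epoch_len_s:
        raise SleepDataError(
            f"cannot collapse {series.epoch_len_s} s epochs into shorter "
            f"{target_len_s} s windows"
        )
    if target_len_s % series.epoch_len_s:
        raise SleepDataError("target epoch length must be a multiple of the source")
    ratio = target_len_s // series.epoch_len_s
    n_full = len(series) // ratio
    if len(series) % ratio:
        warnings.warn(
            f"dropping trailing partial window of {len(series) % ratio} epochs",
            stacklevel=2,
        )
    counts = (
        series.counts[: n_full * ratio].reshape(n_full, ratio).sum(axis=1)
    )
    return CountEpochSeries(
        participant_id=series.participant_id,
        epoch_start=series.epoch_start[: n_full * ratio : ratio],
        counts=counts,
        epoch_len_s=target_len_s,
    )


def binarize_stages(hyp: Hypnogram) -> Hypnogram:
    """Collapse AASM stages to binary: W -> Wake; N1/N2/N3/REM -> Sleep."""
    binary = np.array([STAGE_TO_BINARY[s] for s in hyp.stage], dtype=object)
    return Hypnogram(
        participant_id=hyp.participant_id,
        epoch_start=hyp.epoch_start,
        stage=binary,
        scorable=hyp.scorable.copy(),
        lights_out=hyp.lights_out,
    )


def downsample_hypnogram_to_minutes(hyp: Hypnogram) -> MinuteStates:
    """Take the first 30 s epoch of each minute as that minute's value.

    Minutes pair epochs (0,1), (2,3), ... from the first epoch; a minute
    is scorable only if its first epoch is scorable (the representative
    value is otherwise undefined).  A trailing unpaired epoch is dropped
    with a warning.
    """
    if not hyp.is_binary:
        hyp = binarize_stages(hyp)
    n_pairs = len(hyp) // 2
    if len(hyp) % 2:
        warnings.warn("dropping trailing unpaired 30 s epoch", stacklevel=2)
    first = slice(0, 2 * n_pairs, 2)
    return MinuteStates(
        participant_id=hyp.participant_id,
        minute_start=hyp.epoch_start[first],
        sleep=np.array([s == "Sleep" for s in hyp.stage[first]]),
        scorable=hyp.scorable[first].copy(),
    )


def align_night(
    psg: MinuteStates, ag: MinuteStates, lights_out
) -> AlignedNight:
    """Inner-join PSG and actigraph minutes and locate Time in Bed.

    TIB starts at the first minute at/after lights-out (a mid-minute
    lights-out rounds forward) and ends at the Awake anchor: the last
    included PSG minute scored Sleep.  Minutes where PSG is unscorable
    are excluded from both streams.
    """
    common = psg.minute_start.intersection(ag.minute_start)
    if len(common) == 0:
        raise SleepDataError("no overlapping minutes between PSG and actigraph")
    pi = psg.minute_start.get_indexer(common)
    ai = ag.minute_start.get_indexer(common)
    psg_sleep = psg.sleep[pi]
    ag_sleep = ag.sleep[ai]
    included = psg.scorable[pi] & ag.scorable[ai]

    tib_start = int(np.searchsorted(common.asi8, pd.Timestamp(lights_out).value))
    if tib_start >= len(common):
        raise NoSleepError("lights-out falls after the aligned night")
    anchor_candidates = np.nonzero(psg_sleep & included)[0]
    anchor_candidates = anchor_candidates[anchor_candidates >= tib_start]
    if anchor_candidates.size == 0:
        raise NoSleepError("no scorable PSG sleep minute after lights-out")
    tib_end = int(anchor_candidates[-1])

    pid = psg.participant_id or ag.participant_id
    return AlignedNight(
        participant_id=pid,
        minute_start=common,
        psg_sleep=psg_sleep,
        ag_sleep=ag_sleep,
        included=included,
        tib_start_idx=tib_start,
        tib_end_idx=tib_end,
    )
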