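"""Cole–Kripke sleep/wake scoring of 60 s activity-count epochs.

The classifier computes, for each minute *i*, a weighted sum over a
window spanning four minutes before to two minutes after::

    a_i = min(counts_i / scale, cap)
    D_i = P * (w[-4]*a_{i-4} + ... + w[0]*a_i + w[+1]*a_{i+1} + w[+2]*a_{i+2})

and scores Sleep when ``D_i < threshold`` (a tie scores Wake).  Windows
extending past the series boundary treat missing neighbours as zero, so
the output has the same length as the input.

The original publication's coefficients exist in several device- and
epoch-length-specific dialects; the defaults below are the 60 s-epoch
dialect in common use for wrist ActiGraph counts, and every coefficient
is overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CountEpochSeries, MinuteStates, SleepDataError


@dataclass(frozen=True)
class ColeKripkeParams:
    """Coefficients of the weighted-window classifier.

    ``weights`` are ordered (w-4, w-3, w-2, w-1, w0, w+1, w+2).
    """

    scale: float = 100.0
    cap: float = 300.0
    multiplier: float = 0.001
    weights: tuple = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if len(self.weights) != 7:
            raise SleepDataError("exactly 7 window weights required")
        if self.scale <= 0 or self.cap <= 0 or self.multiplier <= 0:
            raise SleepDataError("scale, cap and multiplier must be positive")


DEFAULT_PARAMS = ColeKripkeParams()


@dataclass
class ScoredSeries:
    """Per-minute classifier scores and binary states (True = Sleep)."""

    participant_id: str
    minute_start: pd.DatetimeIndex
    score: np.ndarray
    sleep: np.ndarray
    included: np.ndarray

    def __len__(self) -> int:
        return len(self.score)

    def to_minutes(self) -> MinuteStates:
        return MinuteStates(
            participant_id=self.participant_id,
            minute_start=self.minute_start,
            sleep=self.sleep.copy(),
            scorable=self.included.copy(),
        )


def cole_kripke(
    series: CountEpochSeries, params: Optional[ColeKripkeParams] = None
) -> ScoredSeries:
    """Score a contiguous 60 s count series as Sleep/Wake.

    Raises if the series is not at 60 s epochs — collapse first with
    :func:`actisleep.io_alignment.collapse_epochs`.
    """
    params = params or DEFAULT_PARAMS
    if series.epoch_len_s != 60:
        raise SleepDataError(
            f"Cole–Kripke requires 60 s epochs, got {series.epoch_len_s} s; "
            "collapse_epochs() first"
        )
    a = np.minimum(series.counts / params.scale, params.cap)
    padded = np.pad(a, (4, 2))
    w = np.asarray(params.weights, dtype=float)
    # correlate(padded, w)[i] = sum_m w[m] * a[i + m - 4]  (m = 0..6)
    score = params.multiplier * np.correlate(padded, w, mode="valid")
    return ScoredSeries(
        participant_id=series.participant_id,
        minute_start=series.epoch_start,
        score=score,
        sleep=score < params.threshold,
        included=np.ones(len(score), dtype=bool),
    )


def score_night(
    series: CountEpochSeries,
    params: Optional[ColeKripkeParams] = None,
    exclusion_mask: Optional[Sequence[bool]] = None,
) -> ScoredSeries:
    """Score a night, then flag excluded minutes.

    Scoring always runs on the full contiguous series — the sliding
    window needs contiguous neighbours — and exclusion is applied
    afterwards as an analysis mask (True = excluded).
    """
    scored = cole_kripke(series, params)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask, dtype=bool)
        if len(mask) != len(scored):
            raise SleepDataError(
                f"exclusion mask length {len(mask)} != series length {len(scored)}"
            )
        scored.included = ~mask
        if not scored.included.any():
            warnings.warn("every minute of the night is excluded", stacklevel=2)
    return scored
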