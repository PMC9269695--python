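"""Sleep-onset rules and the five sleep measures.

Sleep onset under rule *k* is the first minute beginning a run of at
least *k* consecutive Sleep minutes.  Within Time in Bed (TIB, counted
over included minutes):

* SOL  = Wake minutes before onset
* TST  = Sleep minutes from onset through the TIB end
* WASO = Wake minutes from onset through the TIB end
* SE   = 100 * TST / TIB
* SE_ASLEEP = 100 * TST / (TIB - SOL)

Isolated Sleep minutes before onset (possible when k > 1) belong to no
measure; they are reported as ``pre_onset_sleep_min`` so that
SOL + TST + WASO + pre-onset sleep = TIB.  Excluded minutes contribute
to nothing and break a candidate sleep run.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AlignedNight, SleepDataError, SleepMetrics

METRIC_NAMES = ("TST", "SOL", "WASO", "SE", "SE_ASLEEP")
DEFAULT_RULES = (1, 5, 10)


def detect_sleep_onset(sleep: Sequence[bool], k: int) -> Optional[int]:
    """Index of the first minute starting >= k consecutive Sleep minutes."""
    if k < 1:
        raise SleepDataError("onset rule k must be >= 1")
    sleep = np.asarray(sleep, dtype=bool)
    run = 0
    for i, s in enumerate(sleep):
        run = run + 1 if s else 0
        if run >= k:
            return i - k + 1
    return None


def _onset_masked(
    sleep: np.ndarray, included: np.ndarray, k: int
) -> Optional[int]:
    """Onset scan where excluded minutes break a run and count nowhere."""
    run = 0
    for i in range(len(sleep)):
        if not included[i]:
            run = 0
        elif sleep[i]:
            run += 1
            if run >= k:
                return i - k + 1
        else:
            run = 0
    return None


def compute_metrics(
    night: AlignedNight, device: str, rule: int
) -> SleepMetrics:
    """Five sleep measures for one night, device stream and onset rule.

    ``device`` selects the PSG or AG stream.  When no onset exists the
    night is all-wake by construction of the measures: SOL spans every
    included Wake minute in TIB, TST = WASO = 0, SE = 0 and SE_ASLEEP is
    undefined (None).
    """
    if device == "PSG":
        states = night.psg_sleep
    elif device == "AG":
        states = night.ag_sleep
    else:
        raise SleepDataError(f"unknown device {device!r} (expected 'PSG' or 'AG')")
    sl = night.tib_slice
    sleep = states[sl]
    inc = night.included[sl]
    tib = int(inc.sum())
    if tib == 0:
        raise SleepDataError("night has zero included minutes within TIB")

    onset = _onset_masked(sleep, inc, rule)
    if onset is None:
        sol = int((inc & ~sleep).sum())
        pre = int((inc & sleep).sum())
        return SleepMetrics(
            tib_min=tib,
            onset_idx=None,
            sol_min=sol,
            tst_min=0,
            waso_min=0,
            se_pct=0.0,
            se_asleep_pct=None,
            pre_onset_sleep_min=pre,
        )

    before_inc = inc[:onset]
    before_sleep = sleep[:onset]
    sol = int((before_inc & ~before_sleep).sum())
    pre = int((before_inc & before_sleep).sum())
    after_inc = inc[onset:]
    after_sleep = sleep[onset:]
    tst = int((after_inc & after_sleep).sum())
    waso = int((after_inc & ~after_sleep).sum())
    se = 100.0 * tst / tib
    se_asleep = 100.0 * tst / (tib - sol)
    return SleepMetrics(
        tib_min=tib,
        onset_idx=onset,
        sol_min=sol,
        tst_min=tst,
        waso_min=waso,
        se_pct=se,
        se_asleep_pct=se_asleep,
        pre_onset_sleep_min=pre,
    )


def metrics_table(
    nights: Iterable[AlignedNight], rules: Sequence[int] = DEFAULT_RULES
) -> pd.DataFrame:
    """Long table of all measures: participant x device x rule x metric.

    One row per (participant, device, rule, metric); 2 devices x
    len(rules) x 5 metrics rows per night.
    """
    nights = list(nights)
    if not nights:
        raise SleepDataError("metrics_table requires at least one night")
    rows = []
    for night in nights:
        for device in ("PSG", "AG"):
            for rule in rules:
                try:
                    m = compute_metrics(night, device, rule)
                except SleepDataError as exc:
                    raise SleepDataError(
                        f"participant {night.participant_id}: {exc}"
                    ) from exc
                for name, value in m.as_dict().items():
                    rows.append(
                        {
                            "participant": night.participant_id,
                            "device": device,
                            "rule": int(rule),
                            "metric": name,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def metrics_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each measure keyed by (device, rule, metric)."""
    def q1(x):
        return x.quantile(0.25)

    def q3(x):
        return x.quantile(0.75)

    out = (
        table.groupby(["device", "rule", "metric"])["value"]
        .agg(median="median", iqr_low=q1, iqr_high=q3)
        .reset_index()
    )
    return out
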