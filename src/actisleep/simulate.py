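"""Synthetic paired PSG/actigraph nights with known ground truth.

Each night is built at minute resolution: a lights-out wake run (the
true sleep-onset latency), then a consolidated sleep period interrupted
by brief awakenings, ending on a Sleep minute (the Awake anchor).  The
hypnogram duplicates each minute into two 30 s epochs, with Sleep
minutes optionally relabelled to AASM stages; activity counts emulate
the signal an actigraph sees:

* restless wake -> gamma-distributed high counts,
* quiet wake    -> near-zero counts (the motionless lying-awake minutes
  that actigraphy notoriously misreads as sleep),
* sleep         -> zero counts except occasional movement bursts.

Occasional unscorable PSG blocks are injected to exercise the exclusion
path.  All randomness flows from the config seed, so any night is
reproducible end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    CountEpochSeries,
    Hypnogram,
    SleepDataError,
    SleepMetrics,
    minute_range,
)

DEFAULT_START = pd.Timestamp("2024-03-01 23:00:00")


@dataclass(frozen=True)
class CountDist:
    """Small family of non-negative integer distributions.

    ``kind`` is one of ``point`` (constant = mean), ``poisson``,
    ``nbinom`` (mean/dispersion parameterisation; variance
    mean + mean^2/dispersion) or ``geometric`` (support >= 1,
    p = 1/mean).
    """

    kind: str
    mean: float
    dispersion: float = math.inf

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "point":
            return int(round(self.mean))
        if self.kind == "poisson":
            return int(rng.poisson(self.mean))
        if self.kind == "geometric":
            return int(rng.geometric(min(1.0, 1.0 / max(self.mean, 1.0))))
        if self.kind == "nbinom":
            k = self.dispersion
            if not math.isfinite(k):
                return int(rng.poisson(self.mean))
            p = k / (k + self.mean)
            return int(rng.negative_binomial(k, p))
        raise SleepDataError(f"unknown distribution kind {self.kind!r}")

    def scaled(self, factor: float) -> "CountDist":
        return replace(self, mean=self.mean * factor)


@dataclass(frozen=True)
class NightConfig:
    """Generator settings for one synthetic night (minutes throughout).

    Defaults describe a healthy young adult: ~8 h in bed, mean true SOL
    20 min, about six brief awakenings (WASO ~24 min, so sleep
    efficiency > 90%), and mostly motionless wake
    (``quiet_wake_prob``) — the stated driver of low actigraph
    specificity.
    """

    tib_target_min: int = 480
    sol_true: CountDist = CountDist("nbinom", 20.0, 2.5)
    n_awakenings: CountDist = CountDist("poisson", 6.0)
    awakening_len_min: CountDist = CountDist("geometric", 4.0)
    quiet_wake_prob: float = 0.85
    sleep_move_prob: float = 0.05
    active_count_level: float = 800.0
    burst_count_level: float = 150.0
    quiet_count_level: float = 2.0
    unscorable_block_prob: float = 0.3
    unscorable_block_len: CountDist = CountDist("geometric", 40.0)
    epoch_len_s: int = 60
    stage_proportions: Tuple[Tuple[str, float], ...] = (
        ("N1", 0.05),
        ("N2", 0.55),
        ("N3", 0.15),
        ("REM", 0.25),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("quiet_wake_prob", "sleep_move_prob", "unscorable_block_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SleepDataError(f"{name} must lie in [0, 1]")
        if self.tib_target_min < self.sol_true.mean + 1:
            raise SleepDataError("tib_target_min must exceed mean SOL")
        if self.epoch_len_s not in (1, 60):
            raise SleepDataError("counts are emitted at 1 s or 60 s epochs")

    @property
    def expected_sleep_fraction(self) -> float:
        expected_waso = self.n_awakenings.mean * self.awakening_len_min.mean
        return max(
            0.0, (self.tib_target_min - self.sol_true.mean - expected_waso)
        ) / self.tib_target_min


@dataclass
class SyntheticNight:
    """One generated night: signals, latent truth and its bookkeeping."""

    participant_id: str
    hypnogram: Hypnogram
    counts: CountEpochSeries
    lights_out: pd.Timestamp
    truth: SleepMetrics
    truth_minutes: np.ndarray  # noiseless latent states, True = Sleep


def _latent_architecture(
    config: NightConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, int, int]:
    """Minute states plus (sol, waso) bookkeeping from construction."""
    tib = config.tib_target_min
    sol = min(config.sol_true.sample(rng), tib - 2)
    n_awk = config.n_awakenings.sample(rng)
    lens = [config.awakening_len_min.sample(rng) for _ in range(n_awk)]
    waso = int(sum(lens))
    n_sleep = tib - sol - waso
    if n_sleep < n_awk + 1:
        raise SleepDataError(
            f"infeasible config: {n_awk} awakenings totalling {waso} min do not "
            f"fit in a {tib - sol} min sleep span"
        )
    states = np.ones(tib, dtype=bool)
    states[:sol] = False
    if n_awk:
        # choose distinct gaps between sleep minutes: bouts are interior,
        # non-adjacent, and the night still ends on a Sleep minute
        gaps = np.sort(rng.choice(n_sleep - 1, size=n_awk, replace=False))
        seq = []
        prev = 0
        for gap, ln in zip(gaps, lens):
            seq.append(np.ones(gap + 1 - prev, dtype=bool))
            seq.append(np.zeros(ln, dtype=bool))
            prev = gap + 1
        seq.append(np.ones(n_sleep - prev, dtype=bool))
        states[sol:] = np.concatenate(seq)
    return states, sol, waso


def _emit_counts(
    states: np.ndarray, config: NightConfig, rng: np.random.Generator
) -> np.ndarray:
    n = len(states)
    counts = np.zeros(n, dtype=np.int64)
    for i, asleep in enumerate(states):
        if asleep:
            if rng.random() < config.sleep_move_prob:
                counts[i] = int(rng.gamma(2.0, config.burst_count_level / 2.0))
        else:
            if rng.random() < config.quiet_wake_prob:
                counts[i] = int(rng.poisson(config.quiet_count_level))
            else:
                counts[i] = int(rng.gamma(2.0, config.active_count_level / 2.0))
    return counts


def generate_night(
    config: NightConfig,
    participant_id: str = "p01",
    start: pd.Timestamp = DEFAULT_START,
) -> SyntheticNight:
    """Generate one paired night; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    states, sol, waso = _latent_architecture(config, rng)
    tib = len(states)
    tst = tib - sol - waso

    minute_counts = _emit_counts(states, config, rng)
    minutes = minute_range(start, tib)
    if config.epoch_len_s == 60:
        counts = CountEpochSeries(participant_id, minutes, minute_counts, 60)
    else:
        secs = np.concatenate(
            [
                rng.multinomial(c, np.full(60, 1.0 / 60.0))
                for c in minute_counts
            ]
        )
        counts = CountEpochSeries(
            participant_id,
            pd.date_range(start, periods=tib * 60, freq="1s"),
            secs,
            1,
        )

    labels, probs = zip(*config.stage_proportions)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    stage_min = np.where(
        states, rng.choice(labels, size=tib, p=probs), "W"
    ).astype(object)
    stage = np.repeat(stage_min, 2)
    scorable = np.ones(tib, dtype=bool)
    if config.unscorable_block_prob and rng.random() < config.unscorable_block_prob:
        block = min(config.unscorable_block_len.sample(rng), tib - 1)
        s0 = int(rng.integers(0, tib - block + 1))
        scorable[s0 : s0 + block] = False
    hyp = Hypnogram(
        participant_id=participant_id,
        epoch_start=pd.date_range(start, periods=tib * 2, freq="30s"),
        stage=stage,
        scorable=np.repeat(scorable, 2),
        lights_out=start,
    )

    truth = SleepMetrics(
        tib_min=tib,
        onset_idx=sol,
        sol_min=sol,
        tst_min=tst,
        waso_min=waso,
        se_pct=100.0 * tst / tib,
        se_asleep_pct=100.0 * tst / (tib - sol),
        pre_onset_sleep_min=0,
    )
    return SyntheticNight(
        participant_id=participant_id,
        hypnogram=hyp,
        counts=counts,
        lights_out=pd.Timestamp(start),
        truth=truth,
        truth_minutes=states,
    )


@dataclass(frozen=True)
class CohortJitter:
    """Participant-level random effects applied to the night template.

    A participant draws a time-in-bed offset (normal, ``tib_sd_min``),
    log-normal multipliers on mean SOL and awakening frequency, and a
    logit-scale shift of the quiet-wake probability.  A degenerate
    jitter (all SDs zero) removes every source of between-participant
    variation: the cohort collapses to one replicated night.
    """

    tib_sd_min: float = 35.0
    sol_log_sd: float = 0.5
    awakening_log_sd: float = 0.3
    quiet_logit_sd: float = 0.5

    @property
    def varies(self) -> bool:
        return any(
            sd > 0
            for sd in (
                self.tib_sd_min,
                self.sol_log_sd,
                self.awakening_log_sd,
                self.quiet_logit_sd,
            )
        )


def _child_seed(master: int, ordinal: int) -> int:
    """Deterministic per-participant seed (SeedSequence mixing)."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, int(ordinal)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _apply_jitter(
    template: NightConfig, jitter: CohortJitter, rng: np.random.Generator
) -> NightConfig:
    tib = max(
        int(round(template.tib_target_min + rng.normal(0.0, jitter.tib_sd_min)))
        if jitter.tib_sd_min > 0
        else template.tib_target_min,
        int(template.sol_true.mean) + 60,
    )
    sol = template.sol_true.scaled(
        float(rng.lognormal(0.0, jitter.sol_log_sd)) if jitter.sol_log_sd > 0 else 1.0
    )
    awk = template.n_awakenings.scaled(
        float(rng.lognormal(0.0, jitter.awakening_log_sd))
        if jitter.awakening_log_sd > 0
        else 1.0
    )
    q = template.quiet_wake_prob
    if jitter.quiet_logit_sd > 0 and 0.0 < q < 1.0:
        logit = math.log(q / (1.0 - q)) + rng.normal(0.0, jitter.quiet_logit_sd)
        q = 1.0 / (1.0 + math.exp(-logit))
    return replace(template, tib_target_min=tib, sol_true=sol, n_awakenings=awk,
                   quiet_wake_prob=q)


def generate_cohort(
    n_participants: int,
    template: Optional[NightConfig] = None,
    seed: int = 0,
    jitter: CohortJitter = CohortJitter(),
    start: pd.Timestamp = DEFAULT_START,
) -> list:
    """Generate a cohort of paired nights with participant random effects.

    Child seeds derive deterministically from the master ``seed`` and the
    participant ordinal, so the cohort reproduces end to end.
    """
    if n_participants < 1:
        raise SleepDataError("cohort needs at least 1 participant")
    template = template or calibration_profile("healthy_young_adult")
    jr = np.random.default_rng(seed)
    nights = []
    for i in range(n_participants):
        cfg = _apply_jitter(template, jitter, jr)
        cfg = replace(cfg, seed=_child_seed(seed, i if jitter.varies else 0))
        nights.append(generate_night(cfg, participant_id=f"p{i + 1:02d}", start=start))
    return nights


def calibration_profile(name: str) -> NightConfig:
    """Named generator profiles.

    ``healthy_young_adult`` targets the regime typical of PSG validation
    studies in healthy young sleepers: high sleep efficiency (>80%) and
    predominantly motionless wake, under which actigraphy shows high
    sensitivity, low specificity, and over-reads sleep (TST, SE up;
    SOL, WASO down).
    """
    if name == "healthy_young_adult":
        return NightConfig()
    raise SleepDataError(f"unknown calibration profile {name!r}")
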