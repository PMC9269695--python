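# Methods

## Scope and data model

`actisleep` compares two minute-resolution binary sleep/wake series per
night: a criterion series derived from a technician-scored PSG hypnogram
(30 s epochs, AASM stages) and a device series derived from wrist
accelerometer activity counts. Epoch timestamps label the epoch start;
intervals are half-open. The pipeline consumes plain CSV (counts,
hypnogram, lights-out events); proprietary device binaries and raw EEG
are out of scope, as is the conversion of raw accelerations to activity
counts.

## Alignment

PSG minutes take the first 30 s epoch of each pair as the representative
value, pairing from the first epoch rather than snapping to wall-clock
minutes (recordings need not start on a minute boundary). A minute whose
first epoch is unscorable is excluded outright — its representative
value is undefined — and exclusions apply to both streams. The two
streams are inner-joined on minute timestamps. Time in Bed runs from the
first minute at/after lights-out (a mid-minute lights-out rounds
forward) to the Awake anchor, the last included PSG Sleep minute;
terminal wake is outside TIB and never counted.

Actigraph scoring always runs on the full continuous count series
*before* exclusion masking, because the sliding window needs contiguous
neighbours; exclusion is an analysis filter, not a signal gap.

## Cole–Kripke scoring

Counts are rescaled (`scale`, default 100), ceiled (`cap`, default 300),
convolved with a 7-minute weight vector spanning 4 minutes back to
2 minutes forward, and multiplied by `P` (default 0.001); scores below
`threshold` (default 1.0) are Sleep, with ties scored Wake. Windows at
the series edge zero-pad missing neighbours so output length equals
input length (dropping edge epochs would lose the TIB anchors). The
coefficient defaults are the 60 s-epoch dialect in common use for wrist
ActiGraph data; because published dialects differ by device and epoch
length, every coefficient is a parameter and appears in run logs.

## Sleep measures and onset rules

Sleep onset under rule *k* is the first minute beginning a run of ≥ *k*
consecutive Sleep minutes over included minutes; an exclusion gap breaks
a run (the conservative reading — a run is only as long as the evidence
for it). TST counts Sleep minutes from onset onward, so TST can vary
with the rule; isolated pre-onset Sleep minutes (possible when k > 1)
belong to no measure and are surfaced separately so that
SOL + TST + WASO + pre-onset sleep = TIB exactly. SOL counts only Wake
minutes before onset (the literal definition), not all pre-onset
minutes. Nights without onset keep SE = 0 and flag SE_ASLEEP as
undefined rather than dividing by a pre-onset-only denominator.

## Validation statistics

Epoch statistics use Sleep as the positive class and are computed over
included minutes within TIB by default — the window where all the
measures live — with a `full_night` scope preserved as an option. The
headline numbers pool epochs across participants; per-participant
tables are returned alongside. Under the TIB scope the onset rule does
not alter the epoch states, so per-rule agreement tables repeat the
pooled values.

Cohen's *d* is the independent-samples pooled-SD form against the PSG
1 min criterion, signed so that underestimation by the comparator is
positive; a paired variant (mean difference / SD of differences) is
available behind a flag. CIs are bias-corrected percentile bootstrap,
2000 resamples by default, resampling participants jointly to preserve
the pairing; the seed is an argument and is logged. Magnitude labels:
negligible < 0.2 ≤ small < 0.5 ≤ moderate < 0.8 ≤ large.

Bias models are linear mixed models per measure with a participant
random intercept and Device/Rule fixed effects, treatment-coded with
PSG and the 1 min rule as references, so the Device coefficient is
directly the actigraph bias. The Device × Rule interaction is decided
by a likelihood-ratio test on maximum-likelihood fits at α = 0.05 and
the retained model is refit by REML for the reported estimates and
95% Wald CIs. A Rule main-effect LRT (main-effects model vs
device-only) is reported when the interaction is dropped. Zero
between-participant variance is handled at the boundary with a warning.

## Synthetic cohort

The generator builds the latent night at minute resolution — the same
resolution as every downstream comparison — and duplicates minutes into
30 s epochs for the hypnogram (Sleep minutes relabelled N1/N2/N3/REM
i.i.d. by configurable proportions). Architecture: a wake run of length
SOL (negative binomial, mean 20 min, dispersion 2.5), then a sleep span
interrupted by `n_awakenings` (Poisson, mean 6) wake bouts (geometric
lengths, mean 4 min) placed uniformly at interior, non-adjacent
positions, ending on a Sleep minute. Defaults describe a healthy young
adult with ~480 min in bed and sleep efficiency > 90%.

Counts per minute: restless wake → gamma(shape 2, mean 800); quiet wake
(probability `quiet_wake_prob`, default 0.85) → Poisson(2); sleep → 0
except movement bursts (probability 0.05, gamma mean 150). Counts can
alternatively be emitted at 1 s epochs (multinomial split of the minute
total) to exercise the collapsing step. Unscorable PSG blocks are
injected with probability 0.3 per night (geometric length, mean
40 min). Distribution families are pragmatic choices, stated here and
overridable; nothing downstream depends on them beyond the moments.

The quiet-wake probability is the profile's key dial: because the
scoring window sums over seven minutes, wake is detected only where
restless minutes cluster, and 0.85 places pipeline specificity near
25% with sensitivity ≈ 99% — the regime reported for healthy young
adults — while preserving the canonical bias directions (TST and SE
overestimated, SOL and WASO underestimated).

Cohort generation draws participant-level random effects (normal TIB
offset, log-normal multipliers on SOL mean and awakening rate, a
logit-normal shift of quiet-wake probability) from the master seed and
derives per-night child seeds via `SeedSequence([master, ordinal])`. A
degenerate jitter (all SDs zero) removes every source of
between-participant variation by design, collapsing the cohort to one
replicated night — useful for tests that need exact replicates.

What the generator does **not** emulate: ultradian stage cycling and
stage-dependent movement, sleep-disordered breathing arousals,
device-clock drift, non-wear, and naps. Passing tests therefore show
the pipeline's arithmetic and inference are correct and that the
qualitative actigraphy error pattern emerges from quiet wake alone —
not that any particular clinical population will show these exact
numbers.

## Problem sizes and numerical choices

Property tests use 10,000 random binary nights for the measure
invariants, 1000 random series for scorer-oracle equivalence, 200
seeded nights for exact truth recovery, and 200 replicates for LRT
type-I calibration (n = 30 participants each); parameter recovery
injects a +26 min device offset at n = 50. The end-to-end demonstration
uses 19 participants — a typical PSG validation cohort size. LRT
statistics are clipped at zero; bootstrap resamples with undefined
*d* (zero pooled SD) are dropped from the CI; percentile intervals are
widened to contain the point estimate in degenerate cases.

## Known limitations

Single algorithm and wear location; one sleep period per night; no
rescoring rules (e.g. Webster) and no Sadeh/Oakley comparators;
agreement measured without chance correction (no kappa) by design. The
independent-samples Cohen's *d* ignores the pairing, matching the
criterion-vs-comparator framing it reproduces; the paired form is
available where that trade-off is unwanted.
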