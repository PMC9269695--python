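"""Agreement statistics, effect sizes and mixed-effects bias models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actisleep import (
    SleepDataError,
    cohens_d,
    confusion,
    effect_size_grid,
    effect_size_label,
    fit_bias_models,
    metrics_table,
)

from conftest import make_aligned


class TestConfusion:
    def test_two_by_two_by_hand(self):
        # trailing PSG wake lies outside TIB, so compare the full night
        night = make_aligned("SSWW", ag="SSSW")
        pooled, per = confusion([night], scope="full_night")
        assert (pooled.tp, pooled.tn, pooled.fp, pooled.fn) == (2, 1, 1, 0)
        assert pooled.agreement_pct == pytest.approx(75.0)
        assert pooled.sensitivity_pct == pytest.approx(100.0)
        assert pooled.specificity_pct == pytest.approx(50.0)
        assert per["p01"].n == 4

    def test_perfect_agreement(self):
        pooled, _ = confusion([make_aligned("SWSWSS")])
        assert pooled.agreement_pct == 100.0
        assert pooled.sensitivity_pct == 100.0
        assert pooled.specificity_pct == 100.0

    def test_always_sleep_device(self):
        pooled, _ = confusion([make_aligned("SWWSWS", ag="SSSSSS")])
        assert pooled.sensitivity_pct == 100.0
        assert pooled.specificity_pct == 0.0

    def test_no_wake_minutes_specificity_undefined(self):
        pooled, _ = confusion([make_aligned("SSSS")])
        assert pooled.specificity_pct is None

    def test_exclusions_shrink_denominator(self):
        night = make_aligned("SSSSSSSS", ag="SSSSSSSS", included="11101110")
        pooled, _ = confusion([night])
        # TIB ends at the last *included* sleep minute (idx 6); idx 3 excluded
        assert pooled.n == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_is_prevalence_weighted(self, seed):
        rng = np.random.default_rng(seed)
        psg = rng.random(300) < 0.8
        psg[-1] = True
        ag = rng.random(300) < 0.9
        night = make_aligned(
            "".join("S" if s else "W" for s in psg),
            ag="".join("S" if s else "W" for s in ag),
        )
        pooled, _ = confusion([night])
        p = (pooled.tp + pooled.fn) / pooled.n
        mix = pooled.sensitivity_pct * p + pooled.specificity_pct * (1 - p)
        assert pooled.agreement_pct == pytest.approx(mix, abs=1e-9)


class TestCohensD:
    def test_identical_vectors(self):
        res = cohens_d([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.d == 0.0 and res.label == "negligible"

    def test_closed_form_three_points(self):
        res = cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.d == pytest.approx(-1.0)
        assert res.label == "large"

    @pytest.mark.parametrize(
        "d,label",
        [(0.1, "negligible"), (0.3, "small"), (0.6, "moderate"), (0.9, "large"),
         (-0.3, "small"), (0.2, "small"), (0.5, "moderate"), (0.8, "large")],
    )
    def test_magnitude_bands(self, d, label):
        assert effect_size_label(d) == label

    def test_antisymmetry(self):
        a = [1.0, 5.0, 2.0, 8.0]
        b = [2.0, 4.0, 4.0, 9.0]
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 12), rng.normal(11, 2, 12)
        assert cohens_d(a, b).d == pytest.approx(cohens_d(7 * a, 7 * b).d)

    def test_zero_sd_unequal_means_rejected(self):
        with pytest.raises(SleepDataError):
            cohens_d([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 1, 15), rng.normal(6, 1, 15)
        res = cohens_d(a, b, seed=2)
        assert res.ci_low <= res.d <= res.ci_high

    def test_ci_narrows_with_n(self):
        rng = np.random.default_rng(4)
        small = cohens_d(rng.normal(0, 1, 10), rng.normal(0.5, 1, 10), seed=0)
        big = cohens_d(rng.normal(0, 1, 100), rng.normal(0.5, 1, 100), seed=0)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_paired_form(self):
        a = np.array([10.0, 12.0, 14.0, 16.0])
        b = a - np.array([2.0, 1.0, 3.0, 2.0])
        res = cohens_d(a, b, paired=True)
        diff = a - b
        assert res.d == pytest.approx(diff.mean() / diff.std(ddof=1))


def _toy_cohort_table(n=12, sol_shift=0.0, seed=0):
    """Metrics-style long table with controllable AG offsets."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        base = {
            "TST": rng.normal(420, 30),
            "SOL": rng.normal(30, 10),
            "WASO": rng.normal(25, 8),
            "SE": rng.normal(90, 3),
            "SE_ASLEEP": rng.normal(94, 2),
        }
        for device in ("PSG", "AG"):
            for rule in (1, 5, 10):
                for metric, v in base.items():
                    value = v
                    if device == "AG" and metric == "SOL":
                        value = v + sol_shift
                    rows.append(
                        dict(participant=f"p{i:02d}", device=device,
                             rule=rule, metric=metric, value=value)
                    )
    return pd.DataFrame(rows)


class TestEffectSizeGrid:
    def test_identical_devices_all_zero(self):
        grid = effect_size_grid(_toy_cohort_table(), n_boot=200)
        assert np.allclose(grid["d"], 0.0)
        assert len(grid) == 25  # 5 comparisons x 5 metrics

    def test_constant_psg_rules_zero_columns(self):
        grid = effect_size_grid(_toy_cohort_table(), n_boot=200)
        psg = grid[grid["device"] == "PSG"]
        assert np.allclose(psg["d"], 0.0)

    def test_known_sol_offset_yields_d_two(self):
        # AG SOL = PSG SOL - 20 with SD 10 -> d = +2.0 in the SOL column
        table = _toy_cohort_table(n=300, sol_shift=-20.0, seed=5)
        grid = effect_size_grid(table, n_boot=200)
        sol_ag = grid[(grid["metric"] == "SOL") & (grid["device"] == "AG")]
        assert np.allclose(sol_ag["d"], 2.0, atol=0.15)
        assert (sol_ag["label"] == "large").all()

    def test_missing_cell_named(self):
        table = _toy_cohort_table()
        table = table[~((table["device"] == "AG") & (table["rule"] == 10))]
        with pytest.raises(SleepDataError, match="AG/rule 10"):
            effect_size_grid(table, n_boot=50)


def _mixed_table(n, device_offsets, interaction=0.0, participant_sd=30.0,
                 resid_sd=5.0, rule_offsets=(0.0, 0.0, 0.0), seed=0,
                 metrics=("TST",)):
    rng = np.random.default_rng(seed)
    rules = (1, 5, 10)
    rows = []
    for i in range(n):
        b = rng.normal(0, participant_sd)
        for metric in metrics:
            for device in ("PSG", "AG"):
                for rule, roff in zip(rules, rule_offsets):
                    mu = 400 + b + roff
                    if device == "AG":
                        mu += device_offsets.get(metric, 0.0)
                        if rule == 10:
                            mu += interaction
                    rows.append(
                        dict(participant=f"p{i:03d}", device=device, rule=rule,
                             metric=metric, value=mu + rng.normal(0, resid_sd))
                    )
    return pd.DataFrame(rows)


class TestBiasModels:
    def test_recovers_injected_device_offset(self):
        table = _mixed_table(25, {"TST": 26.0}, seed=11)
        res = fit_bias_models(table)["TST"]
        est, lo, hi = res.device_bias
        assert est == pytest.approx(26.0, abs=2.0)
        assert lo <= 26.0 <= hi
        assert not res.interaction_retained

    def test_null_data_small_estimates(self):
        table = _mixed_table(30, {}, seed=21)
        res = fit_bias_models(table)["TST"]
        est, lo, hi = res.device_bias
        assert abs(est) < 3.0
        assert lo <= 0.0 <= hi
        assert not res.interaction_retained
        assert res.rule_lrt_p > 0.05

    def test_detects_interaction(self):
        detected = 0
        for rep in range(10):
            table = _mixed_table(60, {"TST": 10.0}, interaction=10.0,
                                 seed=100 + rep)
            if fit_bias_models(table)["TST"].interaction_retained:
                detected += 1
        assert detected >= 9

    def test_device_sign_convention(self):
        # AG above PSG -> positive Device estimate (overestimation)
        table = _mixed_table(20, {"TST": 15.0}, seed=3)
        assert fit_bias_models(table)["TST"].device_bias[0] > 0

    def test_requires_two_participants(self):
        table = _mixed_table(1, {}, seed=0)
        with pytest.raises(SleepDataError):
            fit_bias_models(table)
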