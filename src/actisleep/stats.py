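"""Agreement statistics, effect sizes and mixed-effects device-bias models.

The sleep-field convention is used throughout: Sleep is the positive
class, so sensitivity is the fraction of PSG Sleep minutes the device
also calls Sleep, and specificity the fraction of PSG Wake minutes it
calls Wake.

Effect sizes are Cohen's *d* with the conventional magnitude bands
(negligible < 0.2, small 0.2–0.49, moderate 0.5–0.79, large >= 0.8),
computed against a criterion measure (PSG with the 1 min onset rule by
default) so that underestimation by the comparator yields positive *d*.

Device/rule bias is estimated with a linear mixed model
``value ~ Device * Rule`` with a random intercept per participant.  The
Device x Rule interaction is kept only if a likelihood-ratio test on
maximum-likelihood fits rejects the reduced model; reported estimates
come from an REML refit of the retained model.  Treatment coding uses
PSG and the 1 min rule as references, so a positive Device estimate
means the actigraph overestimates the measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import AlignedNight, SleepDataError

D_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"))


@dataclass
class EpochAgreement:
    """2x2 confusion counts at the minute level (Sleep = positive)."""

    tp: int  # both Sleep
    tn: int  # both Wake
    fp: int  # AG Sleep, PSG Wake
    fn: int  # AG Wake, PSG Sleep

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def agreement_pct(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def sensitivity_pct(self) -> Optional[float]:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity_pct(self) -> Optional[float]:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    def __add__(self, other: "EpochAgreement") -> "EpochAgreement":
        return EpochAgreement(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion(
    nights: Iterable[AlignedNight], scope: str = "TIB"
) -> Tuple[EpochAgreement, Dict[str, EpochAgreement]]:
    """Pooled and per-participant epoch-by-epoch agreement.

    ``scope='TIB'`` restricts to included minutes between lights-out and
    the Awake anchor (where the sleep measures live); ``'full_night'``
    uses every included aligned minute.
    """
    if scope not in ("TIB", "full_night"):
        raise SleepDataError(f"unknown scope {scope!r}")
    pooled = EpochAgreement(0, 0, 0, 0)
    per: Dict[str, EpochAgreement] = {}
    nights = list(nights)
    if not nights:
        raise SleepDataError("confusion requires at least one night")
    for night in nights:
        sl = night.tib_slice if scope == "TIB" else slice(None)
        inc = night.included[sl]
        psg = night.psg_sleep[sl][inc]
        ag = night.ag_sleep[sl][inc]
        ea = EpochAgreement(
            tp=int(np.sum(psg & ag)),
            tn=int(np.sum(~psg & ~ag)),
            fp=int(np.sum(~psg & ag)),
            fn=int(np.sum(psg & ~ag)),
        )
        per[night.participant_id] = ea
        pooled = pooled + ea
    return pooled, per


def effect_size_label(d: float) -> str:
    for cut, name in D_BANDS:
        if abs(d) < cut:
            return name
    return "large"


@dataclass
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    label: str


def cohens_d(
    criterion_values: Sequence[float],
    comparison_values: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    paired: bool = False,
    ci_level: float = 0.95,
) -> EffectSizeResult:
    """Cohen's *d* of criterion minus comparison with a bootstrap CI.

    The default is the independent-samples pooled-SD form
    ``d = (mean_c - mean_x) / s_pooled`` (denominator n1 + n2 - 2);
    ``paired=True`` uses mean difference over SD of the differences.
    The CI is a bias-corrected percentile bootstrap resampling
    participants jointly (the pairing is preserved).
    """
    c = np.asarray(criterion_values, dtype=float)
    x = np.asarray(comparison_values, dtype=float)
    if len(c) != len(x):
        raise SleepDataError("criterion and comparison must pair per participant")
    if len(c) < 2:
        raise SleepDataError("need at least 2 participants")

    def _d(cv: np.ndarray, xv: np.ndarray) -> float:
        if paired:
            diff = cv - xv
            sd = diff.std(ddof=1)
            if sd == 0:
                if diff.mean() != 0:
                    raise SleepDataError("zero SD of differences with nonzero mean")
                return 0.0
            return diff.mean() / sd
        n1, n2 = len(cv), len(xv)
        pooled = np.sqrt(
            ((n1 - 1) * cv.var(ddof=1) + (n2 - 1) * xv.var(ddof=1)) / (n1 + n2 - 2)
        )
        if pooled == 0:
            if cv.mean() != xv.mean():
                raise SleepDataError("zero pooled SD with unequal means")
            return 0.0
        return (cv.mean() - xv.mean()) / pooled

    d = float(_d(c, x))

    rng = np.random.default_rng(seed)
    n = len(c)
    idx = rng.integers(0, n, size=(n_boot, n))
    cb, xb = c[idx], x[idx]
    if paired:
        diff = cb - xb
        sd = diff.std(ddof=1, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = diff.mean(axis=1) / sd
    else:
        pooled = np.sqrt((cb.var(ddof=1, axis=1) + xb.var(ddof=1, axis=1)) / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = (cb.mean(axis=1) - xb.mean(axis=1)) / pooled
    boot = boot[np.isfinite(boot)]
    if boot.size < 10 or np.ptp(boot) == 0:
        lo = hi = d
    else:
        # bias-corrected percentile interval
        prop = (np.sum(boot < d) + 0.5 * np.sum(boot == d)) / boot.size
        prop = min(max(prop, 1.0 / boot.size), 1 - 1.0 / boot.size)
        z0 = sps.norm.ppf(prop)
        zl = sps.norm.ppf((1 - ci_level) / 2)
        zu = -zl
        a1 = sps.norm.cdf(2 * z0 + zl)
        a2 = sps.norm.cdf(2 * z0 + zu)
        lo, hi = np.quantile(boot, [a1, a2])
        lo, hi = float(min(lo, d)), float(max(hi, d))
    return EffectSizeResult(d=d, ci_low=lo, ci_high=hi, label=effect_size_label(d))


def effect_size_grid(
    table: pd.DataFrame,
    criterion_rule: int = 1,
    rules: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_boot: int = 2000,
    paired: bool = False,
) -> pd.DataFrame:
    """Effect sizes of every device/rule cell against PSG at the 1 min rule.

    Returns one row per (metric, device, rule) comparison with the
    criterion column excluded, i.e. for the standard three rules: PSG at
    5 and 10 min plus AG at 1, 5 and 10 min, for each of the five
    measures.
    """
    if rules is None:
        rules = sorted(table["rule"].unique())
    wide = table.pivot_table(
        index="participant", columns=["device", "rule", "metric"], values="value"
    )
    rows = []
    for metric in pd.unique(table["metric"]):
        key_c = ("PSG", criterion_rule, metric)
        if key_c not in wide.columns:
            raise SleepDataError(f"missing criterion cell PSG/rule {criterion_rule}/{metric}")
        crit = wide[key_c]
        for device in ("PSG", "AG"):
            for rule in rules:
                if device == "PSG" and rule == criterion_rule:
                    continue
                key = (device, rule, metric)
                if key not in wide.columns:
                    raise SleepDataError(f"missing cell {device}/rule {rule}/{metric}")
                comp = wide[key]
                both = pd.concat([crit, comp], axis=1).dropna()
                if len(both) < 2:
                    raise SleepDataError(
                        f"fewer than 2 complete participants for {device}/{rule}/{metric}"
                    )
                res = cohens_d(
                    both.iloc[:, 0].to_numpy(),
                    both.iloc[:, 1].to_numpy(),
                    n_boot=n_boot,
                    seed=seed,
                    paired=paired,
                )
                rows.append(
                    {
                        "metric": metric,
                        "device": device,
                        "rule": rule,
                        "d": res.d,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "label": res.label,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class BiasModelResult:
    """Mixed-model fixed effects for one sleep measure.

    ``fixed_effects`` maps term name -> (estimate, ci_low, ci_high);
    the Device term is the AG - PSG bias.  ``rule_lrt_p`` tests the Rule
    main effect (reduced main-effects model vs device-only model).
    """

    metric: str
    fixed_effects: Dict[str, Tuple[float, float, float]]
    lrt_stat: float
    lrt_p: float
    interaction_retained: bool
    rule_lrt_stat: Optional[float] = None
    rule_lrt_p: Optional[float] = None

    @property
    def device_bias(self) -> Tuple[float, float, float]:
        return self.fixed_effects["device[AG]"]


_DEV = "C(device, Treatment('PSG'))"
_RULE = "C(rule)"


def _rename_term(term: str) -> str:
    term = term.replace(f"{_DEV}[T.", "device[").replace(f"{_RULE}[T.", "rule[")
    return term


def _fit(formula: str, df: pd.DataFrame, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["participant"])
        return model.fit(reml=reml)


def _lrt(df: pd.DataFrame, full: str, reduced: str) -> Tuple[float, float, int]:
    m1 = _fit(full, df, reml=False)
    m0 = _fit(reduced, df, reml=False)
    k = m1.model.k_fe - m0.model.k_fe
    stat = max(0.0, 2.0 * (m1.llf - m0.llf))
    p = float(sps.chi2.sf(stat, k)) if k > 0 else 1.0
    return stat, p, k


def fit_bias_models(
    table: pd.DataFrame, alpha: float = 0.05
) -> Dict[str, BiasModelResult]:
    """Per-metric mixed-model Device and Rule bias estimation.

    For each measure: fit the full model ``value ~ Device * Rule`` and
    the main-effects model by ML, decide the interaction by LRT at
    ``alpha``, refit the retained model by REML and report the fixed
    effects with 95% Wald CIs.  Rows with undefined values (e.g.
    SE_ASLEEP on no-onset nights) are dropped for that measure.
    """
    if table["participant"].nunique() < 2:
        raise SleepDataError("bias models need at least 2 participants")
    full_f = f"value ~ {_DEV} * {_RULE}"
    main_f = f"value ~ {_DEV} + {_RULE}"
    dev_f = f"value ~ {_DEV}"
    out: Dict[str, BiasModelResult] = {}
    for metric, sub in table.groupby("metric", sort=False):
        sub = sub.dropna(subset=["value"]).copy()
        lrt_stat, lrt_p, _ = _lrt(sub, full_f, main_f)
        retained = full_f if lrt_p < alpha else main_f
        fit = _fit(retained, sub, reml=True)
        if np.asarray(fit.cov_re).item() < 1e-8:
            warnings.warn(
                f"{metric}: random-intercept variance estimated at the boundary (~0)",
                stacklevel=2,
            )
        ci = fit.conf_int()
        fe = {}
        for term in fit.fe_params.index:
            fe[_rename_term(term)] = (
                float(fit.fe_params[term]),
                float(ci.loc[term, 0]),
                float(ci.loc[term, 1]),
            )
        rule_stat = rule_p = None
        if retained == main_f:
            rule_stat, rule_p, _ = _lrt(sub, main_f, dev_f)
        out[metric] = BiasModelResult(
            metric=metric,
            fixed_effects=fe,
            lrt_stat=lrt_stat,
            lrt_p=lrt_p,
            interaction_retained=lrt_p < alpha,
            rule_lrt_stat=rule_stat,
            rule_lrt_p=rule_p,
        )
    return out


def bias_models_frame(models: Dict[str, BiasModelResult]) -> pd.DataFrame:
    """Flatten bias-model results to a tidy frame (metric x term)."""
    rows = []
    for metric, res in models.items():
        for term, (est, lo, hi) in res.fixed_effects.items():
            rows.append(
                {
                    "metric": metric,
                    "term": term,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "interaction_retained": res.interaction_retained,
                    "interaction_lrt_p": res.lrt_p,
                    "rule_lrt_p": res.rule_lrt_p,
                }
            )
    return pd.DataFrame(rows)
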