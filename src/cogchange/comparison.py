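"""Two-group comparison statistics.

Decline/improvement rates are compared with Fisher's exact test; effect sizes
are odds ratios with Woolf logit confidence intervals, applying the
Woolf–Haldane correction (add 0.5 to every cell) whenever the 2x2 table
contains a zero. Continuous group contrasts use BCa bootstrap intervals for
the difference in means, and longitudinal group differences use a
group x time interaction model on change scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ContingencyResult",
    "odds_ratio",
    "or_confidence_interval",
    "fisher_exact",
    "contingency_analysis",
    "bca_bootstrap_mean_diff",
    "GroupTimeResult",
    "group_time_glm",
    "or_table",
]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 table (a = patients with event, b = without; c/d controls) with
    odds ratio, Woolf CI, exact p, and whether the Haldane correction fired."""

    a: int
    b: int
    c: int
    d: int
    corrected: bool
    or_value: float
    ci_low: float
    ci_high: float
    p_two_sided: float


def _check_margins(a: int, b: int, c: int, d: int) -> None:
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("both group margins must be positive")


def _cells(a: int, b: int, c: int, d: int) -> tuple[tuple[float, float, float, float], bool]:
    corrected = min(a, b, c, d) == 0
    if corrected:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5), True
    return (float(a), float(b), float(c), float(d)), False


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Odds of the event in patients over controls: (a·d)/(b·c).

    When any cell is zero, 0.5 is added to all four cells (Woolf–Haldane)
    before forming the ratio; the returned flag records the correction.
    """
    _check_margins(a, b, c, d)
    (a_, b_, c_, d_), corrected = _cells(a, b, c, d)
    return (a_ * d_) / (b_ * c_), corrected


def or_confidence_interval(
    a: int, b: int, c: int, d: int, level: float = 0.95, z_value: float | None = None
) -> tuple[float, float]:
    """Woolf logit interval exp(ln OR ± z · sqrt(1/a + 1/b + 1/c + 1/d)),
    computed on the Haldane-corrected cells whenever the correction applies.

    The critical value defaults to the conventional two-decimal normal
    quantile (1.96 at 95%), the value used in published tables; pass
    ``z_value`` to override.
    """
    _check_margins(a, b, c, d)
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    (a_, b_, c_, d_), _ = _cells(a, b, c, d)
    log_or = np.log((a_ * d_) / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = round(float(stats.norm.ppf((1 + level) / 2)), 2) if z_value is None else z_value
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed table's (point-probability convention)."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def contingency_analysis(a: int, b: int, c: int, d: int, level: float = 0.95) -> ContingencyResult:
    or_value, corrected = odds_ratio(a, b, c, d)
    ci_low, ci_high = or_confidence_interval(a, b, c, d, level)
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        corrected=corrected,
        or_value=float(or_value),
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=fisher_exact(a, b, c, d),
    )


def bca_bootstrap_mean_diff(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for mean(x) − mean(y).

    Falls back to the percentile interval (with a warning) when the jackknife
    acceleration is degenerate, e.g. for zero-variance samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples must have size >= 2")
    rng = np.random.default_rng(seed)

    def statistic(xs, ys, axis=-1):
        return np.mean(xs, axis=axis) - np.mean(ys, axis=axis)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.bootstrap(
                (x, y),
                statistic,
                n_resamples=n_boot,
                confidence_level=level,
                method="BCa",
                rng=rng,
            )
            lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        except Exception:
            lo, hi = np.nan, np.nan
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn(
            "degenerate jackknife in BCa bootstrap; falling back to percentile interval",
            stacklevel=2,
        )
        res = stats.bootstrap(
            (x, y),
            statistic,
            n_resamples=n_boot,
            confidence_level=level,
            method="percentile",
            rng=np.random.default_rng(seed),
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    return lo, hi


@dataclass(frozen=True)
class GroupTimeResult:
    """Group x time interaction on a two-timepoint variable.

    ``beta_std``/``p_interaction`` come from the regression of Δ = t2 − t1 on
    (baseline, group, group x baseline) with standardized continuous variables;
    ``f_group``/``p_group`` are the repeated-measures group x time F-test,
    computed as the between-group one-way ANOVA on Δ (exactly the mixed-ANOVA
    interaction for two timepoints).
    """

    beta_std: float
    p_interaction: float
    beta_group_std: float
    p_group_term: float
    f_group: float
    p_group: float


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("constant predictor in group x time model")
    return (v - np.mean(v)) / sd


def group_time_glm(
    values_t1: np.ndarray, values_t2: np.ndarray, group: np.ndarray
) -> GroupTimeResult:
    """Test for a group x time interaction in paired two-timepoint data.

    ``group`` is a binary indicator (1 = patient). Complete data required.
    """
    t1 = np.asarray(values_t1, float)
    t2 = np.asarray(values_t2, float)
    g = np.asarray(group, float)
    if not (len(t1) == len(t2) == len(g)):
        raise ValueError("inputs must have equal length")
    if np.unique(g).size < 2:
        raise ValueError("constant predictor in group x time model")
    delta = t2 - t1
    dz = _zscore(delta) if np.std(delta, ddof=1) > 0 else delta
    t1z = _zscore(t1)
    design = sm.add_constant(np.column_stack([t1z, g, g * t1z]), has_constant="add")
    fit = sm.OLS(dz, design).fit()
    f_group, p_group = stats.f_oneway(delta[g == 1], delta[g == 0])
    return GroupTimeResult(
        beta_std=float(fit.params[3]),
        p_interaction=float(fit.pvalues[3]),
        beta_group_std=float(fit.params[2]),
        p_group_term=float(fit.pvalues[2]),
        f_group=float(f_group),
        p_group=float(p_group),
    )


def or_table(rate_table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Contingency analysis of every (measure, event) row of a rate table.

    Rows where neither group has any event yield no odds ratio (NaN), matching
    the convention of leaving such cells blank.
    """
    rows = []
    for _, r in rate_table.iterrows():
        a = int(r["patient_count"])
        b = int(r["patient_n"]) - a
        c = int(r["control_count"])
        d = int(r["control_n"]) - c
        if a == 0 and c == 0:
            rows.append(
                {
                    "measure": r["measure"], "event": r["event"],
                    "a": a, "b": b, "c": c, "d": d,
                    "corrected": False,
                    "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                }
            )
            continue
        res = contingency_analysis(a, b, c, d, level)
        rows.append(
            {
                "measure": r["measure"], "event": r["event"],
                "a": a, "b": b, "c": c, "d": d,
                "corrected": res.corrected,
                "or": res.or_value, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)
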