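"""Derived endocrine quantities and predictor models of cognitive change.

Free testosterone is computed from total testosterone, SHBG, and albumin via
the mass-action binding equilibrium (Vermeulen's calculated free
testosterone). Change scores (Δ = follow-up − baseline) for hormones,
symptoms, and network values feed simple and adjusted linear regressions of
cognitive change on candidate predictors, including genotype carrier status
and androgen-receptor CAG repeat length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import Group, SubjectRecord

log = logging.getLogger(__name__)

__all__ = [
    "BindingConstants",
    "DeltaRecord",
    "PredictorModelResult",
    "free_testosterone",
    "add_free_testosterone",
    "compute_deltas",
    "delta_summary",
    "predict_change",
    "adjusted_testosterone_model",
    "genotype_effects",
]


@dataclass(frozen=True)
class BindingConstants:
    """Mass-action association constants for testosterone binding.

    Canonical published values: K_SHBG = 1.0e9 L/mol,
    K_albumin = 3.6e4 L/mol; albumin defaults to 43 g/L when not assayed
    (molar mass 66,500 g/mol).
    """

    k_shbg: float = 1.0e9
    k_albumin: float = 3.6e4
    albumin_default: float = 43.0
    albumin_molar_mass: float = 66_500.0

    def __post_init__(self) -> None:
        for f in ("k_shbg", "k_albumin", "albumin_default", "albumin_molar_mass"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class DeltaRecord:
    subject_id: str
    group: Group
    variable_id: str
    delta: float


@dataclass(frozen=True)
class PredictorModelResult:
    outcome_id: str
    predictor_id: str
    group: str | None
    n: int
    beta: float
    p: float
    group_interaction_p: float | None = None
    collinearity_warning: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def free_testosterone(
    total_t: float,
    shbg: float,
    constants: BindingConstants = BindingConstants(),
    albumin: float | None = None,
) -> float:
    """Calculated free testosterone (nmol/L) from the binding equilibrium.

    With N = 1 + K_alb·[albumin] (albumin in mol/L), the free concentration
    FT is the positive root of

        K_shbg·N·FT² + (N + K_shbg·(SHBG − TT))·FT − TT = 0

    with TT and SHBG in mol/L; the result satisfies 0 <= FT <= TT.
    """
    if total_t < 0 or shbg < 0:
        raise ValueError("total testosterone and SHBG must be >= 0")
    if albumin is None:
        albumin = constants.albumin_default
    if albumin < 0:
        raise ValueError("albumin must be >= 0")
    if total_t == 0:
        return 0.0
    tt = total_t * 1e-9
    sh = shbg * 1e-9
    alb_molar = albumin / constants.albumin_molar_mass
    n_factor = 1.0 + constants.k_albumin * alb_molar
    a = constants.k_shbg * n_factor
    b = n_factor + constants.k_shbg * (sh - tt)
    # positive root of a·FT² + b·FT − tt = 0
    ft = (-b + np.sqrt(b * b + 4.0 * a * tt)) / (2.0 * a)
    ft_nmol = float(ft * 1e9)
    return min(ft_nmol, total_t)


def add_free_testosterone(
    subjects: list[SubjectRecord],
    constants: BindingConstants = BindingConstants(),
) -> None:
    """Fill ``free_testosterone`` on both hormone panels of every subject
    that has total testosterone and SHBG measured (in place)."""
    for s in subjects:
        for panel in (s.hormones_t1, s.hormones_t2):
            if panel.total_testosterone is not None and panel.shbg is not None:
                panel.free_testosterone = free_testosterone(
                    panel.total_testosterone, panel.shbg, constants, panel.albumin
                )


def compute_deltas(
    subjects: list[SubjectRecord],
    variables: list[str] | None = None,
) -> list[DeltaRecord]:
    """Δ = t2 − t1 for every hormone (and symptom) variable per subject.

    Subjects missing either timepoint for a variable are skipped with a log
    entry. ``variables`` defaults to all hormone panel fields present plus
    symptom scores.
    """
    records: list[DeltaRecord] = []
    for s in subjects:
        panel_vars = variables
        if panel_vars is None:
            panel_vars = [
                f for f in vars(s.hormones_t1)
                if getattr(s.hormones_t1, f) is not None or getattr(s.hormones_t2, f) is not None
            ] + list(s.symptom_scores)
        for v in panel_vars:
            if v in s.symptom_scores:
                t1, t2 = s.symptom_scores[v]
            else:
                t1 = getattr(s.hormones_t1, v, None)
                t2 = getattr(s.hormones_t2, v, None)
            if t1 is None or t2 is None:
                log.info("skipping delta %s for %s: missing timepoint", v, s.subject_id)
                continue
            records.append(DeltaRecord(s.subject_id, s.group, v, float(t2 - t1)))
    return records


def delta_summary(records: list[DeltaRecord]) -> pd.DataFrame:
    """Group mean (SD) of Δ per variable, the layout of a change-score table."""
    df = pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group.value,
          "variable": r.variable_id, "delta": r.delta} for r in records]
    )
    out = (
        df.groupby(["variable", "group"])["delta"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "delta_mean", "std": "delta_sd", "count": "n"})
    )
    return out


def _simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int]:
    design = sm.add_constant(x, has_constant="add")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), len(y)


def predict_change(
    outcome: np.ndarray,
    predictor: np.ndarray,
    group: np.ndarray | None = None,
    outcome_id: str = "outcome",
    predictor_id: str = "predictor",
    min_n: int = 10,
    alpha: float = 0.05,
) -> list[PredictorModelResult]:
    """Within-group simple linear regression of a change outcome on a predictor.

    When ``group`` is given, one model per group is fitted; any group reaching
    ``alpha`` triggers a pooled follow-up model with group, predictor, and
    group x predictor terms whose interaction p is attached to the results.
    Without ``group``, a single pooled simple regression is fitted.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(predictor, float)
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    if group is None:
        if len(y) < min_n:
            raise ValueError(f"need >= {min_n} complete cases, got {len(y)}")
        beta, p, n = _simple_ols(y, x)
        return [PredictorModelResult(outcome_id, predictor_id, None, n, beta, p)]
    g = np.asarray(group)
    results = []
    any_sig = False
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() < min_n:
            raise ValueError(
                f"need >= {min_n} complete cases in group {label!r}, got {int(mask.sum())}"
            )
        if np.std(x[mask]) == 0:
            raise ValueError(f"constant predictor in group {label!r}")
        beta, p, n = _simple_ols(y[mask], x[mask])
        any_sig = any_sig or p < alpha
        results.append(PredictorModelResult(outcome_id, predictor_id, str(label), n, beta, p))
    interaction_p = None
    if any_sig and len(pd.unique(g)) == 2:
        g01 = (g == pd.unique(g)[0]).astype(float)
        design = sm.add_constant(
            np.column_stack([x, g01, x * g01]), has_constant="add"
        )
        fit = sm.OLS(y, design).fit()
        interaction_p = float(fit.pvalues[3])
        results = [
            PredictorModelResult(
                r.outcome_id, r.predictor_id, r.group, r.n, r.beta, r.p,
                group_interaction_p=interaction_p,
            )
            for r in results
        ]
    return results


def adjusted_testosterone_model(
    outcome: np.ndarray,
    testosterone: np.ndarray,
    shbg: np.ndarray,
    cag: np.ndarray,
    outcome_id: str = "outcome",
    predictor_id: str = "testosterone",
    min_n: int = 10,
    condition_threshold: float = 1e3,
) -> PredictorModelResult:
    """Multiple regression of cognitive change on testosterone adjusting for
    matching SHBG and CAG repeat length; reports the testosterone beta/p.

    Baseline levels and Δ-values are both valid inputs as long as the
    testosterone and SHBG columns match in kind.
    """
    y = np.asarray(outcome, float)
    x = np.column_stack([
        np.asarray(testosterone, float),
        np.asarray(shbg, float),
        np.asarray(cag, float),
    ])
    if len(y) < min_n:
        raise ValueError(f"need >= {min_n} complete cases, got {len(y)}")
    if np.any(np.std(x, axis=0) == 0):
        raise ValueError("constant predictor")
    xz = (x - x.mean(axis=0)) / x.std(axis=0)
    collinear = bool(np.linalg.cond(xz) > condition_threshold)
    if collinear:
        warnings.warn("predictors are nearly collinear; betas are unstable", stacklevel=2)
    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return PredictorModelResult(
        outcome_id=outcome_id,
        predictor_id=predictor_id,
        group=None,
        n=len(y),
        beta=float(fit.params[1]),
        p=float(fit.pvalues[1]),
        collinearity_warning=collinear,
    )


def genotype_effects(
    outcomes: dict[str, np.ndarray],
    carrier_flags: dict[str, np.ndarray],
    min_per_level: int = 1,
) -> list[PredictorModelResult]:
    """Regression of change outcomes on risk-genotype carrier status.

    One simple regression per (outcome, genotype) pair among patients; a
    genotype with an empty carrier or non-carrier level is skipped with a log
    entry. Uncorrected p-values by design (exploratory analyses); apply FDR
    downstream if desired.
    """
    results = []
    for geno, flags in carrier_flags.items():
        f = np.asarray(flags, float)
        n_carrier = int(f.sum())
        if n_carrier < min_per_level or (len(f) - n_carrier) < min_per_level:
            log.info("skipping genotype %s: a carrier level is empty", geno)
            continue
        for oid, y in outcomes.items():
            beta, p, n = _simple_ols(np.asarray(y, float), f)
            results.append(PredictorModelResult(oid, geno, "patient", n, beta, p))
    return results
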