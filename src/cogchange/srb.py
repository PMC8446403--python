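"""Standardized regression-based (SRB) change scores.

Follow-up scores of the control group are regressed on baseline score,
premorbid IQ, and age; every participant's follow-up score is then predicted
from that control equation and the residual is standardized by the control
fit's standard error of estimate (SEE). z-scores at or beyond ±1.64 — the
extreme 5% of the normal distribution at either end — are classified as
clinically significant decline or improvement. The mean of a subject's
direction-harmonized z-scores is the global composite (GCS-z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import Direction, Group, MeasureSpec, SubjectRecord

__all__ = [
    "DEFAULT_THRESHOLD",
    "Category",
    "SRBModel",
    "MeasureChange",
    "ChangeResult",
    "fit_srb",
    "score_subject",
    "harmonize_direction",
    "classify",
    "global_composite",
    "score_cohort",
    "rate_table",
]

#: |z| at which change is called clinically significant (normal 5% tails)
DEFAULT_THRESHOLD = 1.64

_N_PARAMS = 4  # intercept + baseline + IQ + age


class Category(str, Enum):
    DECLINED = "declined"
    STABLE = "stable"
    IMPROVED = "improved"


@dataclass(frozen=True)
class SRBModel:
    """Control-group regression for one measure.

    ``coefficients`` is (intercept, b_baseline, b_iq, b_age) in raw-score
    units; ``see`` is the standard error of estimate,
    sqrt(RSS / (n - 4)), also in raw units.
    """

    measure_id: str
    coefficients: tuple[float, float, float, float]
    see: float
    n_controls: int
    coef_stderr: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.see > 0:
            raise ValueError(f"SEE must be > 0, got {self.see}")
        if self.n_controls <= _N_PARAMS + 1:
            raise ValueError("n_controls must exceed number of parameters + 1")


@dataclass
class MeasureChange:
    measure_id: str
    predicted_t2: float
    z: float
    z_harmonized: float
    category: Category


@dataclass
class ChangeResult:
    subject_id: str
    group: Group
    measures: dict[str, MeasureChange]
    gcs_z: float = field(init=False)
    gcs_category: Category = field(init=False)
    threshold: float = DEFAULT_THRESHOLD
    metastatic: bool | None = None

    def __post_init__(self) -> None:
        self.gcs_z = global_composite(self)
        self.gcs_category = classify(self.gcs_z, self.threshold)


def _design(controls: list[SubjectRecord], measure_id: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.array(
        [[s.scores[measure_id][0], s.premorbid_iq, s.age] for s in controls], float
    )
    y = np.array([s.scores[measure_id][1] for s in controls], float)
    return x, y


def fit_srb(controls: list[SubjectRecord], measure: MeasureSpec) -> SRBModel:
    """OLS fit of control follow-up scores on (baseline, premorbid IQ, age).

    Raises on fewer than 6 controls, a rank-deficient design (e.g. a constant
    predictor), or zero residual variance (SEE would be 0 and z undefined).
    """
    if len(controls) < 6:
        raise ValueError(f"need >= 6 controls to fit SRB model, got {len(controls)}")
    x, y = _design(controls, measure.measure_id)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < _N_PARAMS:
        raise ValueError(
            f"rank-deficient design for {measure.measure_id!r} "
            "(a predictor is constant or collinear)"
        )
    fit = sm.OLS(y, design).fit()
    dof = len(controls) - _N_PARAMS
    see = float(np.sqrt(fit.ssr / dof))
    # a numerically exact fit leaves z undefined (division by ~0)
    if not np.isfinite(see) or see**2 <= 1e-16 * max(float(np.var(y)), 1e-300):
        raise ValueError(f"zero residual variance for {measure.measure_id!r}")
    return SRBModel(
        measure_id=measure.measure_id,
        coefficients=tuple(float(b) for b in fit.params),
        see=see,
        n_controls=len(controls),
        coef_stderr=tuple(float(b) for b in fit.bse),
    )


def score_subject(
    model: SRBModel, subject: SubjectRecord, measure: MeasureSpec
) -> tuple[float, float]:
    """Return (predicted_t2, z) for one subject on one measure.

    z = (actual follow-up − predicted follow-up) / SEE of the control fit.
    """
    if model.see <= 0:
        raise ValueError("model SEE must be positive")
    b0, b1, b2, b3 = model.coefficients
    t1, t2 = subject.scores[measure.measure_id]
    predicted = b0 + b1 * t1 + b2 * subject.premorbid_iq + b3 * subject.age
    z = (t2 - predicted) / model.see
    return float(predicted), float(z)


def harmonize_direction(z: float, direction: Direction) -> float:
    """Flip the sign for lower-is-better measures so positive always means
    improvement."""
    return z if Direction(direction) is Direction.HIGHER_IS_BETTER else -z


def classify(z_harmonized: float, threshold: float = DEFAULT_THRESHOLD) -> Category:
    """Classify a harmonized z: boundary values count as change (<= / >=)."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if z_harmonized <= -threshold:
        return Category.DECLINED
    if z_harmonized >= threshold:
        return Category.IMPROVED
    return Category.STABLE


def global_composite(change: ChangeResult) -> float:
    """GCS-z: arithmetic mean of the subject's harmonized per-measure z."""
    if not change.measures:
        raise ValueError("cannot compute global composite with no scored measures")
    return float(np.mean([m.z_harmonized for m in change.measures.values()]))


def score_cohort(
    subjects: list[SubjectRecord],
    measure_specs: list[MeasureSpec],
    threshold: float = DEFAULT_THRESHOLD,
    models: dict[str, SRBModel] | None = None,
) -> tuple[list[ChangeResult], dict[str, SRBModel]]:
    """Fit SRB models on the cohort's controls and score every subject.

    Pre-fitted ``models`` may be supplied (e.g. for sensitivity re-analyses
    that drop patients: the models depend only on controls and are not
    refitted).
    """
    if models is None:
        controls = [s for s in subjects if s.group is Group.CONTROL]
        models = {spec.measure_id: fit_srb(controls, spec) for spec in measure_specs}
    results = []
    for s in subjects:
        measures = {}
        for spec in measure_specs:
            predicted, z = score_subject(models[spec.measure_id], s, spec)
            zh = harmonize_direction(z, spec.direction)
            measures[spec.measure_id] = MeasureChange(
                measure_id=spec.measure_id,
                predicted_t2=predicted,
                z=z,
                z_harmonized=zh,
                category=classify(zh, threshold),
            )
        results.append(
            ChangeResult(
                subject_id=s.subject_id,
                group=s.group,
                measures=measures,
                threshold=threshold,
                metastatic=s.metastatic,
            )
        )
    return results, models


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1) if n else float("nan")


def rate_table(
    changes: list[ChangeResult],
    exclude_metastatic: bool = False,
) -> pd.DataFrame:
    """Per-measure decline/improvement counts and percentages by group.

    Output mirrors the conventional frequency-table layout: one row per
    (measure, event) with patient/control counts, group sizes, and percentages
    rounded to one decimal. An ``overall`` row classifies the GCS-z with the
    same threshold. ``exclude_metastatic`` drops metastatic patients (a
    sensitivity re-analysis; control-based models are unchanged).
    """
    if exclude_metastatic:
        changes = [c for c in changes if not (c.group is Group.PATIENT and c.metastatic)]
    patients = [c for c in changes if c.group is Group.PATIENT]
    controls = [c for c in changes if c.group is Group.CONTROL]
    measure_ids = list(changes[0].measures) if changes else []
    rows = []
    for mid in measure_ids + ["overall"]:
        for event in (Category.DECLINED, Category.IMPROVED):
            def count(group: list[ChangeResult]) -> int:
                if mid == "overall":
                    return sum(c.gcs_category is event for c in group)
                return sum(c.measures[mid].category is event for c in group)

            a, c = count(patients), count(controls)
            rows.append(
                {
                    "measure": mid,
                    "event": event.value,
                    "patient_count": a,
                    "patient_n": len(patients),
                    "patient_pct": _pct(a, len(patients)),
                    "control_count": c,
                    "control_n": len(controls),
                    "control_pct": _pct(c, len(controls)),
                }
            )
    return pd.DataFrame(rows)
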