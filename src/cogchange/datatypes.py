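"""Core data model for a two-group, two-timepoint cognitive/endocrine cohort.

A cohort consists of patients and healthy controls, each assessed at baseline
(t1) and follow-up (t2) on a battery of neuropsychological measures, a serum
hormone panel, and a set of genotype flags; a subset additionally carries a
structural brain connectivity matrix per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Group",
    "Timepoint",
    "Direction",
    "MeasureSpec",
    "GenotypeFlags",
    "HormonePanel",
    "SubjectRecord",
    "Connectome",
    "SYMMETRY_TOL",
]

#: maximum tolerated absolute asymmetry when reading a connectivity matrix
SYMMETRY_TOL = 1e-6


class Group(str, Enum):
    """Cohort arm: cancer patients versus healthy controls."""

    PATIENT = "patient"
    CONTROL = "control"


class Timepoint(str, Enum):
    T1 = "t1"
    T2 = "t2"


class Direction(str, Enum):
    """Scoring direction of a cognitive measure.

    Timed tests (e.g. trail-making, in seconds) and error counts are
    ``LOWER_IS_BETTER``; accuracy/recall scores are ``HIGHER_IS_BETTER``.
    """

    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class MeasureSpec:
    measure_id: str
    domain: str
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class GenotypeFlags:
    """Risk-allele carrier status and androgen-receptor CAG repeat length.

    Carriers of at least one APOE e4 allele, at least one COMT Val allele,
    and BDNF Val homozygotes are the conventional risk classifications.
    """

    apoe_e4_carrier: bool | None = None
    comt_val_carrier: bool | None = None
    bdnf_val_val: bool | None = None
    ar_cag_repeat_length: int | None = None

    def __post_init__(self) -> None:
        if self.ar_cag_repeat_length is not None and self.ar_cag_repeat_length <= 0:
            raise ValueError("ar_cag_repeat_length must be > 0 when present")


# hormone variables carried at both timepoints, in file/table order
HORMONE_VARS = (
    "total_testosterone",  # nmol/L
    "estradiol",  # pmol/L
    "lh",  # IU/L
    "fsh",  # IU/L
    "shbg",  # nmol/L
    "hemoglobin",  # mmol/L
    "erythrocytes",  # volume fraction
    "neutrophils",  # 10^9/L
)


@dataclass
class HormonePanel:
    """One timepoint's serum panel.

    ``free_testosterone`` is derived (mass-action equilibrium), never read
    from file; ``albumin`` is optional and defaulted downstream when absent.
    """

    total_testosterone: float | None = None
    estradiol: float | None = None
    lh: float | None = None
    fsh: float | None = None
    shbg: float | None = None
    albumin: float | None = None
    hemoglobin: float | None = None
    erythrocytes: float | None = None
    neutrophils: float | None = None
    free_testosterone: float | None = None

    def __post_init__(self) -> None:
        for name in HORMONE_VARS + ("albumin",):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"hormone {name} must be >= 0, got {v}")
        if (
            self.free_testosterone is not None
            and self.total_testosterone is not None
            and self.free_testosterone > self.total_testosterone
        ):
            raise ValueError("free testosterone cannot exceed total testosterone")


@dataclass
class SubjectRecord:
    """One participant: group, covariates, and paired t1/t2 measurements."""

    subject_id: str
    group: Group
    age: float
    premorbid_iq: float
    scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    hormones_t1: HormonePanel = field(default_factory=HormonePanel)
    hormones_t2: HormonePanel = field(default_factory=HormonePanel)
    genotype: GenotypeFlags = field(default_factory=GenotypeFlags)
    metastatic: bool | None = None
    symptom_scores: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")

    def score(self, measure_id: str, timepoint: Timepoint | str) -> float:
        t1, t2 = self.scores[measure_id]
        return t1 if Timepoint(timepoint) is Timepoint.T1 else t2


@dataclass
class Connectome:
    """Labelled weighted symmetric connectivity matrix for one subject-timepoint.

    Nodes are atlas regions (90 by default); weights are nonnegative structural
    connection strengths with a zero diagonal, taken as supplied by upstream
    tractography.
    """

    subject_id: str
    timepoint: Timepoint
    node_labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {w.shape}")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError(
                f"{len(self.node_labels)} node labels for a {w.shape[0]}-node matrix"
            )
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
        if np.any(w < 0):
            raise ValueError("connectivity weights must be nonnegative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return replace(self, weights=weights)


def split_by_group(
    subjects: list[SubjectRecord],
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Return (patients, controls) preserving input order."""
    patients = [s for s in subjects if s.group is Group.PATIENT]
    controls = [s for s in subjects if s.group is Group.CONTROL]
    return patients, controls


def group_sizes(subjects: list[SubjectRecord]) -> Mapping[str, int]:
    patients, controls = split_by_group(subjects)
    return {"patient": len(patients), "control": len(controls)}
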