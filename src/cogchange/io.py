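"""Read/write the subject table, connectivity matrices, and result tables.

Subject tables are wide CSV: one row per subject, paired columns
``<measure_id>_t1`` / ``<measure_id>_t2`` for every cognitive measure,
hormone and symptom variable. Connectivity matrices are plain delimited
square numeric text, one file per subject-timepoint.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    HORMONE_VARS,
    SYMMETRY_TOL,
    Connectome,
    GenotypeFlags,
    Group,
    HormonePanel,
    MeasureSpec,
    SubjectRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "read_connectome",
    "write_connectome",
    "write_results",
]

_GENOTYPE_BOOL_COLS = ("apoe_e4_carrier", "comt_val_carrier", "bdnf_val_val")


def _require_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna()
    if bad.any() or raw.isna().any():
        row = int(np.flatnonzero(converted.isna())[0])
        raise ValueError(
            f"non-numeric or missing value in column {column!r}, row {row} "
            f"(value={raw.iloc[row]!r})"
        )
    return converted.astype(float)


def read_subject_table(
    path: str | Path,
    measure_specs: Sequence[MeasureSpec],
    symptom_ids: Sequence[str] = (),
) -> list[SubjectRecord]:
    """Read a wide-format subject CSV into :class:`SubjectRecord` objects.

    Every declared measure must be present at both timepoints; hormone and
    genotype columns are optional as a block but validated when present.
    Missing cells are an error — the reader does not impute.
    """
    df = pd.read_csv(path)
    for required in ("subject_id", "group", "age", "premorbid_iq"):
        if required not in df.columns:
            raise ValueError(f"subject table is missing required column {required!r}")

    measure_cols: dict[str, tuple[pd.Series, pd.Series]] = {}
    for spec in measure_specs:
        cols = (f"{spec.measure_id}_t1", f"{spec.measure_id}_t2")
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"subject table is missing measure column {c!r}")
        measure_cols[spec.measure_id] = (
            _require_numeric(df, cols[0]),
            _require_numeric(df, cols[1]),
        )

    symptom_cols: dict[str, tuple[pd.Series, pd.Series]] = {}
    for sid in symptom_ids:
        cols = (f"{sid}_t1", f"{sid}_t2")
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"subject table is missing symptom column {c!r}")
        symptom_cols[sid] = (_require_numeric(df, cols[0]), _require_numeric(df, cols[1]))

    hormone_present = {
        v: all(f"{v}_{tp}" in df.columns for tp in ("t1", "t2")) for v in HORMONE_VARS
    }
    for v, present in hormone_present.items():
        if present:
            _require_numeric(df, f"{v}_t1")
            _require_numeric(df, f"{v}_t2")

    age = _require_numeric(df, "age")
    iq = _require_numeric(df, "premorbid_iq")

    valid_groups = {g.value for g in Group}
    records: list[SubjectRecord] = []
    for i, row in df.iterrows():
        if row["group"] not in valid_groups:
            raise ValueError(
                f"unknown group label {row['group']!r} in row {i}; "
                f"expected one of {sorted(valid_groups)}"
            )
        scores = {
            mid: (float(t1.iloc[i]), float(t2.iloc[i]))
            for mid, (t1, t2) in measure_cols.items()
        }
        symptoms = {
            sid: (float(t1.iloc[i]), float(t2.iloc[i]))
            for sid, (t1, t2) in symptom_cols.items()
        }
        panels = {}
        for tp in ("t1", "t2"):
            kwargs: dict[str, float] = {}
            for v in HORMONE_VARS:
                if hormone_present[v]:
                    kwargs[v] = float(row[f"{v}_{tp}"])
            if f"albumin_{tp}" in df.columns and pd.notna(row[f"albumin_{tp}"]):
                kwargs["albumin"] = float(row[f"albumin_{tp}"])
            panels[tp] = HormonePanel(**kwargs)
        geno_kwargs: dict[str, Any] = {}
        for c in _GENOTYPE_BOOL_COLS:
            if c in df.columns and pd.notna(row[c]):
                geno_kwargs[c] = bool(row[c])
        if "ar_cag_repeat_length" in df.columns and pd.notna(row["ar_cag_repeat_length"]):
            geno_kwargs["ar_cag_repeat_length"] = int(row["ar_cag_repeat_length"])
        metastatic = None
        if "metastatic" in df.columns and pd.notna(row["metastatic"]):
            metastatic = bool(row["metastatic"])
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=Group(row["group"]),
                age=float(age.iloc[i]),
                premorbid_iq=float(iq.iloc[i]),
                scores=scores,
                hormones_t1=panels["t1"],
                hormones_t2=panels["t2"],
                genotype=GenotypeFlags(**geno_kwargs),
                metastatic=metastatic,
                symptom_scores=symptoms,
            )
        )
    return records


def write_subject_table(
    subjects: Sequence[SubjectRecord],
    path: str | Path,
    float_format: str = "%.17g",
) -> Path:
    """Write subjects as wide CSV, the inverse of :func:`read_subject_table`."""
    rows = []
    for s in subjects:
        row: dict[str, Any] = {
            "subject_id": s.subject_id,
            "group": s.group.value,
            "age": s.age,
            "premorbid_iq": s.premorbid_iq,
        }
        if s.metastatic is not None:
            row["metastatic"] = int(s.metastatic)
        g = s.genotype
        for c in _GENOTYPE_BOOL_COLS:
            v = getattr(g, c)
            if v is not None:
                row[c] = int(v)
        if g.ar_cag_repeat_length is not None:
            row["ar_cag_repeat_length"] = g.ar_cag_repeat_length
        for mid, (t1, t2) in s.scores.items():
            row[f"{mid}_t1"] = t1
            row[f"{mid}_t2"] = t2
        for sid, (t1, t2) in s.symptom_scores.items():
            row[f"{sid}_t1"] = t1
            row[f"{sid}_t2"] = t2
        for tp, panel in (("t1", s.hormones_t1), ("t2", s.hormones_t2)):
            for v in HORMONE_VARS:
                val = getattr(panel, v)
                if val is not None:
                    row[f"{v}_{tp}"] = val
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=float_format)
    return path


def read_connectome(
    path: str | Path,
    labels: Sequence[str],
    subject_id: str | None = None,
    timepoint: str | None = None,
) -> Connectome:
    """Read a delimited square matrix as a :class:`Connectome`.

    Accepts whitespace- or comma-delimited text. The matrix is symmetrized as
    (M + Mᵀ)/2 when the asymmetry is within ``SYMMETRY_TOL`` and rejected
    otherwise; the diagonal is forced to zero.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    m = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path.name}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    asym = float(np.max(np.abs(m - m.T))) if m.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"{path.name}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}"
        )
    if np.any(m < 0):
        raise ValueError(f"{path.name}: negative connectivity weight")
    if subject_id is None or timepoint is None:
        # filename convention <subject_id>_<t1|t2>.<ext>
        stem = path.stem
        sid, _, tp = stem.rpartition("_")
        subject_id = subject_id or sid
        timepoint = timepoint or tp
    return Connectome(
        subject_id=subject_id,
        timepoint=timepoint,
        node_labels=list(labels),
        weights=m,
    )


def write_connectome(conn: Connectome, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{conn.subject_id}_{conn.timepoint.value}.txt"
    np.savetxt(path, conn.weights, fmt="%.17g")
    return path


def _config_hash(config: Any) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: Any = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Write one CSV per result table plus a JSON run manifest.

    Re-running with the same tables/config/seed produces byte-identical files;
    the manifest records the config hash and seed for provenance.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    files: dict[str, str] = {}
    for name in sorted(tables):
        fname = f"{name}.csv"
        tables[name].to_csv(out_dir / fname, index=False, float_format="%.10g")
        files[name] = fname
        log.info("wrote table %s (%d rows)", fname, len(tables[name]))
    manifest = {
        "tables": files,
        "n_tables": len(files),
        "seed": seed,
        "config_hash": _config_hash(config) if config is not None else None,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
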