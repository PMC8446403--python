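"""End-to-end orchestration: simulate → SRB → compare → connectome →
endocrine → report, with a single config and reproducible outputs."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import comparison, connectome, endocrine, io, simulate, srb
from .datatypes import Group, MeasureSpec, SubjectRecord

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters for a full pipeline run."""

    out_dir: Path = Path("cogchange_out")
    seed: int = 0
    threshold: float = srb.DEFAULT_THRESHOLD
    exclude_metastatic: bool = False
    density_grid: connectome.DensityGrid = field(default_factory=connectome.DensityGrid)
    n_random: int = 20
    run_connectome: bool = True
    cohort: simulate.CohortConfig | None = None
    binding_constants: endocrine.BindingConstants = field(
        default_factory=endocrine.BindingConstants
    )

    def resolved_cohort(self) -> simulate.CohortConfig:
        return self.cohort or simulate.default_config(seed=self.seed)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage on a synthetic cohort and write all result tables.

    Returns the tables; identical config+seed yields byte-identical outputs.
    """
    cohort_cfg = config.resolved_cohort()
    _stage("simulate")
    subjects, _truth = simulate.generate_cohort(cohort_cfg)
    specs = cohort_cfg.measure_specs()

    _stage("srb")
    changes, models = srb.score_cohort(subjects, specs, threshold=config.threshold)
    change_rows = []
    for ch in changes:
        for mid, mc in ch.measures.items():
            change_rows.append(
                {"subject_id": ch.subject_id, "group": ch.group.value, "measure": mid,
                 "predicted_t2": mc.predicted_t2, "z": mc.z,
                 "z_harmonized": mc.z_harmonized, "category": mc.category.value}
            )
        change_rows.append(
            {"subject_id": ch.subject_id, "group": ch.group.value, "measure": "gcs",
             "predicted_t2": np.nan, "z": ch.gcs_z, "z_harmonized": ch.gcs_z,
             "category": ch.gcs_category.value}
        )
    tables: dict[str, pd.DataFrame] = {"change_scores": pd.DataFrame(change_rows)}
    rates = srb.rate_table(changes, exclude_metastatic=config.exclude_metastatic)
    tables["rate_table"] = rates

    _stage("compare")
    tables["or_table"] = comparison.or_table(rates)

    if config.run_connectome:
        _stage("connectome")
        conns = simulate.generate_connectomes(cohort_cfg, subjects)
        seed_seq = np.random.SeedSequence((config.seed, 2))
        child_seeds = seed_seq.generate_state(len(conns)) % np.int64(2**31 - 1)
        metric_sets = [
            connectome.subject_metrics(
                conn, grid=config.density_grid, n_random=config.n_random,
                seed=int(child_seeds[i]),
            )
            for i, conn in enumerate(conns.values())
        ]
        groups = {s.subject_id: s.group.value for s in subjects}
        auc_frame = connectome.metric_auc_frame(metric_sets, groups)
        tables["network_auc"] = auc_frame
        tables["network_tests"] = connectome.network_group_analysis(auc_frame)

    _stage("endocrine")
    endocrine.add_free_testosterone(subjects, config.binding_constants)
    deltas = endocrine.compute_deltas(subjects)
    tables["endocrine_deltas"] = endocrine.delta_summary(deltas)
    tables["predictor_models"] = _predictor_models(subjects, changes, config)

    _stage("report")
    cfg_dict = dataclasses.asdict(config, dict_factory=_safe_dict)
    cfg_dict.pop("out_dir", None)  # the destination is not part of the analysis
    io.write_results(tables, config.out_dir, config=cfg_dict, seed=config.seed)
    return tables


def _safe_dict(items: list[tuple[str, Any]]) -> dict[str, Any]:
    return {k: (str(v) if isinstance(v, Path) else v) for k, v in items}


def _predictor_models(
    subjects: list[SubjectRecord],
    changes: list[srb.ChangeResult],
    config: RunConfig,
) -> pd.DataFrame:
    """Exploratory predictor regressions among patients: baseline/Δ hormones,
    symptom Δs, and CAG repeat length against the global composite z."""
    gcs = {c.subject_id: c.gcs_z for c in changes}
    patients = [s for s in subjects if s.group is Group.PATIENT]
    y = np.array([gcs[s.subject_id] for s in patients])
    rows = []

    def run(pid: str, x: np.ndarray) -> None:
        try:
            res = endocrine.predict_change(
                y, x, outcome_id="gcs_z", predictor_id=pid, min_n=6
            )[0]
        except ValueError as exc:
            log.info("skipping predictor %s: %s", pid, exc)
            return
        rows.append({"outcome": res.outcome_id, "predictor": res.predictor_id,
                     "n": res.n, "beta": res.beta, "p": res.p})

    h1 = [s.hormones_t1 for s in patients]
    h2 = [s.hormones_t2 for s in patients]
    run("baseline_total_testosterone", np.array([p.total_testosterone for p in h1]))
    run("baseline_free_testosterone", np.array([p.free_testosterone for p in h1]))
    run("delta_total_testosterone",
        np.array([b.total_testosterone - a.total_testosterone for a, b in zip(h1, h2)]))
    run("delta_free_testosterone",
        np.array([b.free_testosterone - a.free_testosterone for a, b in zip(h1, h2)]))
    run("delta_estradiol", np.array([b.estradiol - a.estradiol for a, b in zip(h1, h2)]))
    run("cag_repeat_length",
        np.array([s.genotype.ar_cag_repeat_length for s in patients], float))
    for sid in patients[0].symptom_scores:
        run(f"delta_{sid}",
            np.array([s.symptom_scores[sid][1] - s.symptom_scores[sid][0] for s in patients]))

    geno = endocrine.genotype_effects(
        {"gcs_z": y},
        {
            g: np.array([getattr(s.genotype, g) for s in patients], float)
            for g in ("apoe_e4_carrier", "comt_val_carrier", "bdnf_val_val")
        },
    )
    for r in geno:
        rows.append({"outcome": r.outcome_id, "predictor": r.predictor_id,
                     "n": r.n, "beta": r.beta, "p": r.p})
    return pd.DataFrame(rows)
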