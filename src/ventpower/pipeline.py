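"""End-to-end analysis pipeline.

Chains ingestion (or synthetic generation), eligibility, outcome accounting,
window aggregation, group comparisons, correlations, and cross-validated
diagnostic evaluation; writes the result tables plus a machine-readable
metrics file. Identical seed and inputs give a byte-identical metrics file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from . import outcomes as oc
from . import stats as st
from .indexes import predicted_body_weight
from .simulate import GeneratorConfig, SyntheticCohort, generate_cohort
from .types import (AnalysisConfig, INDEX_NAMES, PatientCourse, Recipient,
                    VentRecord)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def outcome_table(courses: dict[str, PatientCourse]) -> pd.DataFrame:
    rows = []
    for pid in sorted(courses):
        s = oc.summarize_course(courses[pid])
        rows.append({
            "patient_id": s.patient_id,
            "total_invasive_h": s.total_invasive_h,
            "scenario": s.scenario,
            "pmv_72": s.pmv_72, "pmv_96": s.pmv_96, "pmv_7d": s.pmv_7d,
            "weaning_readiness_h": s.weaning_readiness_h,
            "extubated": s.extubated, "reintubated": s.reintubated,
            "tracheostomy": s.tracheostomy, "nirs": s.nirs,
        })
    return pd.DataFrame(rows)


def aggregate_table(records: Sequence[VentRecord],
                    courses: dict[str, PatientCourse],
                    recipients: dict[str, Recipient],
                    config: AnalysisConfig) -> pd.DataFrame:
    """Per-patient median index panel over the observation window."""
    by_patient: dict[str, list[VentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    rows = []
    skipped = 0
    for pid in sorted(by_patient):
        if pid not in courses or pid not in recipients:
            continue
        rec = recipients[pid]
        pbw = predicted_body_weight(rec.sex, rec.height_m)
        window = oc.observation_window(
            sorted(by_patient[pid], key=lambda r: r.t_h), courses[pid],
            config.window_h)
        if not window:
            skipped += 1
            continue
        agg = oc.aggregate_indexes(window, pbw,
                                   config.aggregate_before_derive)
        row = {"patient_id": pid, "n_records_used": agg.n_records_used,
               "pbw_kg": pbw}
        row.update(agg.indexes)
        rows.append(row)
    if skipped:
        logger.warning("%d patients had no analyzable records in the "
                       "observation window", skipped)
    return pd.DataFrame(rows)


def _pmv_column(threshold_h: float) -> str:
    return {72.0: "pmv_72", 96.0: "pmv_96", 168.0: "pmv_7d"}.get(
        threshold_h, "pmv_72")


def evaluate_indexes(values: pd.DataFrame, outcomes: pd.DataFrame,
                     config: AnalysisConfig,
                     index_names: Sequence[str] = INDEX_NAMES
                     ) -> dict[str, pd.DataFrame]:
    """Correlations, AUROC and repeated-CV diagnostic table per index."""
    merged = values.merge(outcomes, on="patient_id", how="inner")
    threshold_col = _pmv_column(config.pmv_threshold_h)
    if threshold_col in merged.columns:
        labels = merged[threshold_col].astype(int).to_numpy()
    else:
        labels = (merged["total_invasive_h"]
                  > config.pmv_threshold_h).astype(int).to_numpy()
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise PipelineError("degenerate outcome: only one class present")
    duration = merged["total_invasive_h"].to_numpy(dtype=float)
    names = [n for n in index_names if n in merged.columns]

    corr_rows, roc_rows = [], []
    for name in names:
        x = merged[name].to_numpy(dtype=float)
        sp = st.spearman_with_ci(x, duration, config.alpha)
        corr_rows.append({"index": name, "rho": sp.rho, "ci_low": sp.ci_low,
                          "ci_high": sp.ci_high, "n": sp.n,
                          "p_value": sp.p_value})
        roc = st.auroc(x, labels, config.index_orientation[name],
                       config.alpha)
        roc_rows.append({"index": name, "auroc": roc.auroc,
                         "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                         "n_pos": roc.n_pos, "n_neg": roc.n_neg})
    cv = st.repeated_cv_evaluate(
        merged[names], labels, config.index_orientation,
        repeats=config.cv_repeats, folds=config.cv_folds, seed=config.seed,
        alpha=config.alpha)
    return {"correlations": pd.DataFrame(corr_rows),
            "roc": pd.DataFrame(roc_rows),
            "cv_table": cv.table(),
            "fold_assignments": cv.fold_assignments}


def group_comparison_table(values: pd.DataFrame, outcomes: pd.DataFrame,
                           config: AnalysisConfig,
                           index_names: Sequence[str] = INDEX_NAMES
                           ) -> pd.DataFrame:
    merged = values.merge(outcomes, on="patient_id", how="inner")
    col = _pmv_column(config.pmv_threshold_h)
    lab = merged[col].astype(bool)
    rows = []
    for name in index_names:
        if name not in merged.columns:
            continue
        pos = merged.loc[lab, name].to_numpy(dtype=float)
        neg = merged.loc[~lab, name].to_numpy(dtype=float)
        stat, p = st.group_compare(pos, neg, kind="ranksum")
        rows.append({
            "index": name,
            "median_pmv": float(np.median(pos)),
            "q1_pmv": float(np.percentile(pos, 25)),
            "q3_pmv": float(np.percentile(pos, 75)),
            "median_non_pmv": float(np.median(neg)),
            "q1_non_pmv": float(np.percentile(neg, 25)),
            "q3_non_pmv": float(np.percentile(neg, 75)),
            "statistic": stat, "p_value": p,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig, out_dir: Path | str,
                 input_paths: Optional[dict[str, str]] = None,
                 generator_config: Optional[GeneratorConfig] = None,
                 ) -> dict:
    """Run all stages and write the report bundle under ``out_dir``.

    Provide either ``input_paths`` (keys: records, episodes, events,
    recipients) or a ``generator_config`` for a synthetic cohort.
    """
    config.validate()
    out = Path(out_dir)
    if (input_paths is None) == (generator_config is None):
        raise PipelineError("provide input files or a generator request, "
                            "not both")

    if input_paths is not None:
        records, courses, recipients, ingest = cio.read_cohort(
            input_paths["records"], input_paths["episodes"],
            input_paths["events"], input_paths["recipients"])
        manifest = {"source": "files", "ingest": {
            "accepted": ingest.accepted, "rejected": ingest.rejected}}
        index_values = None
    else:
        cohort = generate_cohort(generator_config, config.seed)
        records = cohort.records or []
        courses = {c.patient_id: c for c in cohort.courses}
        recipients = {r.patient_id: r for r in cohort.recipients}
        index_values = cohort.index_values
        manifest = {"source": "generator", "generator": cohort.manifest}

    eligible, tally = cio.apply_eligibility(recipients)
    if not eligible:
        raise PipelineError("empty eligible cohort")
    eligible_set = set(eligible)
    courses = {pid: c for pid, c in courses.items() if pid in eligible_set}

    outcomes = outcome_table(courses)
    if index_values is not None:
        values = index_values[index_values.patient_id.isin(eligible_set)]
        values = values.drop(columns=[c for c in ("group", "duration_h")
                                      if c in values.columns])
    else:
        records = [r for r in records if r.patient_id in eligible_set]
        values = aggregate_table(records, courses, recipients, config)

    comparisons = group_comparison_table(values, outcomes, config)
    evaluation = evaluate_indexes(values, outcomes, config)

    out.mkdir(parents=True, exist_ok=True)
    values.to_csv(out / "aggregates.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    comparisons.to_csv(out / "group_comparisons.csv", index=False)
    evaluation["correlations"].to_csv(out / "correlations.csv", index=False)
    evaluation["roc"].to_csv(out / "roc.csv", index=False)
    evaluation["cv_table"].to_csv(out / "cv_report.csv", index=False)

    col = _pmv_column(config.pmv_threshold_h)
    metrics = {
        "n_eligible": len(eligible),
        "exclusions": tally,
        "pmv_prevalence": float(outcomes[col].mean()),
        "median_duration_pmv_h": float(
            outcomes.loc[outcomes[col], "total_invasive_h"].median()),
        "median_duration_non_pmv_h": float(
            outcomes.loc[~outcomes[col], "total_invasive_h"].median()),
        "spearman": {r["index"]: {"rho": r["rho"], "ci_low": r["ci_low"],
                                  "ci_high": r["ci_high"]}
                     for _, r in evaluation["correlations"].iterrows()},
        "auroc": {r["index"]: {"auroc": r["auroc"], "ci_low": r["ci_low"],
                               "ci_high": r["ci_high"]}
                  for _, r in evaluation["roc"].iterrows()},
        "cv_mean_threshold": {
            r["index"]: r["threshold"]
            for _, r in evaluation["cv_table"].iterrows()},
        "manifest": manifest,
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return metrics
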