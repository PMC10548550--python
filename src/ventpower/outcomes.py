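"""Outcome accounting and within-window aggregation.

Invasive ventilation duration is the sum over all invasive episodes
(endotracheal tube or tracheal cannula alike); prolonged mechanical
ventilation (PMV) is a strict ``> threshold`` label on that total, with 72 h
as the primary definition and 96 h / 7 d as sensitivity thresholds.

Four clinical scenarios partition the courses:

1. successfully extubated at the first attempt;
2. extubation failure (>=1 reintubation) but finally extubated, no
   tracheostomy;
3. tracheostomy after one or more failed extubations;
4. tracheostomy without any preceding extubation ("primary tracheostomy").
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .indexes import RecordIndexes, derive_record_indexes
from .types import (CourseSummary, InvariantError, PatientCourse, VentRecord,
                    INDEX_NAMES, RAW_VARIABLES)

logger = logging.getLogger(__name__)

HOURS_96 = 96.0
HOURS_7D = 168.0


def total_invasive_duration(
        episodes: Sequence[tuple[float, float, str]]) -> float:
    """Total invasive ventilation in hours, summed over all episodes."""
    prev_end = None
    total = 0.0
    for start, end, _interface in episodes:
        if end <= start:
            raise InvariantError("episode end must follow start")
        if prev_end is not None and start < prev_end:
            raise InvariantError("overlapping episodes")
        total += end - start
        prev_end = end
    return total


def label_pmv(total_invasive_h: float, threshold_h: float) -> bool:
    """Strictly-greater PMV label; exactly at the threshold is negative."""
    if total_invasive_h < 0 or threshold_h <= 0:
        raise ValueError("durations and thresholds must be positive")
    return bool(total_invasive_h > threshold_h)


def classify_scenario(course: PatientCourse) -> int:
    """Map a course to one of the four weaning scenarios (see module doc)."""
    extubated = len(course.extubation_times_h) > 0
    reintubated = len(course.reintubation_times_h) > 0
    trach = course.tracheostomy_time_h is not None
    if trach:
        return 3 if extubated else 4
    if not extubated:
        raise InvariantError(
            f"course {course.patient_id}: no extubation and no tracheostomy "
            "— cannot classify (death/censoring not modeled)")
    return 2 if reintubated else 1


def weaning_readiness_time(course: PatientCourse) -> Optional[float]:
    """Hours to the first pressure-controlled -> pressure-support switch."""
    return course.first_ps_transition_h


def classify_nirs(course: PatientCourse) -> bool:
    """Non-invasive respiratory support per the protocolised definition.

    True iff some NHFC/NIV session starts within 24 h after the *first*
    extubation and runs for at least 6 h daily.
    """
    if not course.extubation_times_h:
        return False
    first_ext = min(course.extubation_times_h)
    return any(
        first_ext <= s.start_h <= first_ext + 24.0 and s.daily_hours >= 6.0
        for s in course.nirs_sessions)


def summarize_course(course: PatientCourse) -> CourseSummary:
    """Full outcome panel for one course."""
    course.validate()
    total = total_invasive_duration(course.episodes)
    return CourseSummary(
        patient_id=course.patient_id,
        total_invasive_h=total,
        scenario=classify_scenario(course),
        pmv_72=label_pmv(total, 72.0),
        pmv_96=label_pmv(total, HOURS_96),
        pmv_7d=label_pmv(total, HOURS_7D),
        weaning_readiness_h=weaning_readiness_time(course),
        extubated=len(course.extubation_times_h) > 0,
        reintubated=len(course.reintubation_times_h) > 0,
        tracheostomy=course.tracheostomy_time_h is not None,
        nirs=classify_nirs(course),
    )


def observation_window(records: Sequence[VentRecord], course: PatientCourse,
                       window_h: float = 36.0) -> list[VentRecord]:
    """Records eligible for aggregation.

    Keeps pressure-controlled records up to ``window_h`` after ICU admission,
    or up to the first extubation when it occurs earlier; the bound is
    inclusive.
    """
    cut = window_h
    if course.extubation_times_h:
        first_ext = min(course.extubation_times_h)
        if first_ext < window_h:
            cut = first_ext
    return [r for r in records if r.mode == "PCV" and r.t_h <= cut]


@dataclass(frozen=True)
class PatientAggregate:
    """Per-patient medians of indexes and raw variables over the window."""

    patient_id: str
    n_records_used: int
    indexes: dict[str, float]
    raw: dict[str, float]


def aggregate_indexes(records_in_window: Sequence[VentRecord], pbw_kg: float,
                      aggregate_before_derive: bool = False
                      ) -> PatientAggregate:
    """Median index panel for one patient.

    Default route: derive the panel per record, then take per-index medians.
    The alternative (``aggregate_before_derive``) medians the raw variables
    first and derives the panel once from them; medians do not compose, so
    the two routes differ in general.
    """
    if not records_in_window:
        raise ValueError("no analyzable records in observation window")
    pid = records_in_window[0].patient_id
    raw_med = {}
    for var in RAW_VARIABLES:
        vals = [getattr(r, var) for r in records_in_window]
        vals = [v for v in vals if v is not None]
        raw_med[var] = statistics.median(vals) if vals else float("nan")
    if aggregate_before_derive:
        proto = records_in_window[0]
        ve = raw_med["ve_lmin"]
        median_record = VentRecord(
            patient_id=pid, t_h=proto.t_h, mode="PCV",
            fio2=raw_med["fio2"], rr=raw_med["rr"], vt_ml=raw_med["vt_ml"],
            ppeak=raw_med["ppeak"], peep=raw_med["peep"],
            pao2=raw_med["pao2"], paco2=raw_med["paco2"], ph=raw_med["ph"],
            ve_lmin=None if np.isnan(ve) else ve)
        panel = derive_record_indexes(median_record, pbw_kg)
        idx_med = {k: getattr(panel, k) for k in INDEX_NAMES}
    else:
        panels = [derive_record_indexes(r, pbw_kg) for r in records_in_window]
        idx_med = {k: statistics.median(getattr(p, k) for p in panels)
                   for k in INDEX_NAMES}
    return PatientAggregate(patient_id=pid,
                            n_records_used=len(records_in_window),
                            indexes=idx_med, raw=raw_med)


def patient_quartile_panel(records_in_window: Sequence[VentRecord],
                           pbw_kg: float) -> Optional[pd.DataFrame]:
    """Per-quartile index medians for one patient.

    The patient's window records are split into four bins at the
    within-patient time quantile cut points; each bin contributes the median
    of each derived index. Returns None (and the caller logs the exclusion)
    when fewer than 4 records are available.
    """
    if len(records_in_window) < 4:
        return None
    recs = sorted(records_in_window, key=lambda r: r.t_h)
    times = np.array([r.t_h for r in recs])
    cuts = np.quantile(times, [0.25, 0.5, 0.75])
    bins = np.searchsorted(cuts, times, side="left")  # 0..3
    panels = [derive_record_indexes(r, pbw_kg) for r in recs]
    rows = []
    for q in range(4):
        members = [p for p, b in zip(panels, bins) if b == q]
        if not members:
            # heavy timestamp ties can empty a bin; such patients are
            # excluded below, like those with <4 records
            continue
        row = {"quartile": q + 1}
        row.update({k: statistics.median(getattr(p, k) for p in members)
                    for k in INDEX_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) < 4:
        return None
    return df


def time_quartile_trajectories(
        records_by_patient: dict[str, Sequence[VentRecord]],
        pbw_by_patient: dict[str, float],
        group_by_patient: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level index trajectories over within-patient time quartiles.

    Returns ``(per_subject, per_group)``: the per-subject quartile panel in
    long form (input to the mixed ANOVA) and the across-patient median per
    group x quartile x index.
    """
    subject_rows = []
    excluded = 0
    for pid, recs in records_by_patient.items():
        panel = patient_quartile_panel(recs, pbw_by_patient[pid])
        if panel is None:
            excluded += 1
            continue
        panel = panel.copy()
        panel["patient_id"] = pid
        panel["group"] = group_by_patient[pid]
        subject_rows.append(panel)
    if excluded:
        logger.info("trajectory analysis: %d patients excluded "
                    "(<4 records in window)", excluded)
    if not subject_rows:
        raise ValueError("no patients with >=4 records for trajectories")
    per_subject = pd.concat(subject_rows, ignore_index=True)
    long = per_subject.melt(
        id_vars=["patient_id", "group", "quartile"],
        value_vars=list(INDEX_NAMES), var_name="index", value_name="value")
    per_group = (long.groupby(["group", "quartile", "index"])["value"]
                 .median().rename("median").reset_index())
    return per_subject, per_group
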