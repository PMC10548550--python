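"""CSV cohort ingestion and output.

One canonical dialect: comma-separated, UTF-8, header row required, decimal
point. Rows violating a domain invariant are dropped and counted, not fatal
— retrospective extractions are messy and the analysis must surface, not
hide, how many rows were rejected.

Schemas
-------
records.csv    patient_id,t_h,mode,fio2,rr,vt_ml,ve_lmin,ppeak,peep,pao2,paco2,ph
episodes.csv   patient_id,start_h,end_h,interface
events.csv     patient_id,event_type,time_h,nirs_type,daily_hours
recipients.csv patient_id,sex,height_m,weight_kg,exclusion_flags,<covariates...>
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .types import (AnalysisConfig, EXCLUSION_FLAGS, InvariantError,
                    NirsSession, PatientCourse, Recipient, VentRecord)

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "t_h", "mode", "fio2", "rr", "vt_ml",
                  "ve_lmin", "ppeak", "peep", "pao2", "paco2", "ph"]
EPISODE_COLUMNS = ["patient_id", "start_h", "end_h", "interface"]
EVENT_COLUMNS = ["patient_id", "event_type", "time_h", "nirs_type",
                 "daily_hours"]
RECIPIENT_COLUMNS = ["patient_id", "sex", "height_m", "weight_kg",
                     "exclusion_flags"]
EVENT_TYPES = ("extubation", "reintubation", "tracheostomy", "ps_transition",
               "nirs")


class SchemaError(ValueError):
    """Input file does not conform to the declared schema."""


@dataclass
class IngestReport:
    """Accepted/rejected row accounting per input file."""

    accepted: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, Counter] = field(default_factory=dict)

    def note(self, file: str, ok: int, bad: Counter) -> None:
        self.accepted[file] = ok
        self.rejected[file] = sum(bad.values())
        self.reasons[file] = bad
        if bad:
            logger.warning("%s: rejected %d rows (%s)", file,
                           sum(bad.values()), dict(bad))


def _require_columns(df: pd.DataFrame, needed: Sequence[str],
                     file: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{file}: missing required column(s) {missing}")


def _read_csv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def _float_or_none(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) \
            or (isinstance(value, str) and not value.strip()):
        return None
    return float(value)


def read_records(path: Path | str, report: IngestReport
                 ) -> list[VentRecord]:
    df = _read_csv(path)
    _require_columns(df, [c for c in RECORD_COLUMNS if c != "ve_lmin"],
                     str(path))
    out: list[VentRecord] = []
    bad: Counter = Counter()
    for i, row in df.iterrows():
        try:
            rec = VentRecord(
                patient_id=str(row["patient_id"]), t_h=float(row["t_h"]),
                mode=str(row["mode"]), fio2=float(row["fio2"]),
                rr=float(row["rr"]), vt_ml=float(row["vt_ml"]),
                ppeak=float(row["ppeak"]), peep=float(row["peep"]),
                pao2=float(row["pao2"]), paco2=float(row["paco2"]),
                ph=float(row["ph"]),
                ve_lmin=_float_or_none(row.get("ve_lmin")))
            rec.validate()
        except InvariantError as exc:
            bad[str(exc)] += 1
            continue
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{path}: unparsable value at data row {i + 1}: {exc}"
            ) from exc
        out.append(rec)
    report.note("records", len(out), bad)
    return out


def read_courses(episodes_path: Path | str, events_path: Path | str,
                 report: IngestReport) -> dict[str, PatientCourse]:
    """Assemble PatientCourses from the episodes and events files."""
    epi = _read_csv(episodes_path)
    _require_columns(epi, EPISODE_COLUMNS, str(episodes_path))
    ev = _read_csv(events_path)
    _require_columns(ev, ["patient_id", "event_type", "time_h"],
                     str(events_path))

    episodes: dict[str, list] = defaultdict(list)
    bad_epi: Counter = Counter()
    for i, row in epi.iterrows():
        try:
            start, end = float(row["start_h"]), float(row["end_h"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{episodes_path}: unparsable value at data row {i + 1}: {exc}"
            ) from exc
        if end <= start:
            bad_epi["episode end must follow start"] += 1
            continue
        episodes[str(row["patient_id"])].append(
            (start, end, str(row["interface"])))

    courses: dict[str, PatientCourse] = {}
    for pid, eps in episodes.items():
        courses[pid] = PatientCourse(patient_id=pid,
                                     episodes=sorted(eps))

    bad_ev: Counter = Counter()
    n_ev = 0
    for i, row in ev.iterrows():
        pid = str(row["patient_id"])
        etype = str(row["event_type"])
        if etype not in EVENT_TYPES:
            bad_ev[f"unknown event type {etype!r}"] += 1
            continue
        try:
            t = float(row["time_h"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{events_path}: unparsable value at data row {i + 1}: {exc}"
            ) from exc
        course = courses.setdefault(pid, PatientCourse(patient_id=pid))
        if etype == "extubation":
            course.extubation_times_h.append(t)
        elif etype == "reintubation":
            course.reintubation_times_h.append(t)
        elif etype == "tracheostomy":
            course.tracheostomy_time_h = t
        elif etype == "ps_transition":
            if (course.first_ps_transition_h is None
                    or t < course.first_ps_transition_h):
                course.first_ps_transition_h = t
        else:  # nirs
            course.nirs_sessions.append(NirsSession(
                type=str(row.get("nirs_type", "NIV")), start_h=t,
                daily_hours=float(row.get("daily_hours", 0.0))))
        n_ev += 1

    ok: dict[str, PatientCourse] = {}
    bad_course: Counter = Counter()
    for pid, course in courses.items():
        try:
            course.validate()
        except InvariantError as exc:
            bad_course[str(exc)] += 1
            continue
        ok[pid] = course
    report.note("episodes", sum(len(c.episodes) for c in ok.values()),
                bad_epi + bad_course)
    report.note("events", n_ev, bad_ev)
    return ok


def read_recipients(path: Path | str, report: IngestReport
                    ) -> dict[str, Recipient]:
    df = _read_csv(path)
    _require_columns(df, [c for c in RECIPIENT_COLUMNS
                          if c != "exclusion_flags"], str(path))
    covariate_cols = [c for c in df.columns if c not in RECIPIENT_COLUMNS]
    out: dict[str, Recipient] = {}
    bad: Counter = Counter()
    for i, row in df.iterrows():
        raw_flags = row.get("exclusion_flags")
        if raw_flags is None or pd.isna(raw_flags) or not str(raw_flags).strip():
            flags: frozenset[str] = frozenset()
        else:
            flags = frozenset(f.strip() for f in str(raw_flags).split(";")
                              if f.strip())
        try:
            rec = Recipient(
                patient_id=str(row["patient_id"]), sex=str(row["sex"]),
                height_m=float(row["height_m"]),
                weight_kg=float(row["weight_kg"]),
                covariates={c: float(row[c]) for c in covariate_cols
                            if not pd.isna(row[c])},
                exclusion_flags=flags)
            rec.validate()
        except InvariantError as exc:
            bad[str(exc)] += 1
            continue
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{path}: unparsable value at data row {i + 1}: {exc}"
            ) from exc
        out[rec.patient_id] = rec
    report.note("recipients", len(out), bad)
    return out


def read_cohort(records_path, episodes_path, events_path, recipients_path
                ) -> tuple[list[VentRecord], dict[str, PatientCourse],
                           dict[str, Recipient], IngestReport]:
    report = IngestReport()
    records = read_records(records_path, report)
    courses = read_courses(episodes_path, events_path, report)
    recipients = read_recipients(recipients_path, report)
    return records, courses, recipients, report


def apply_eligibility(recipients: dict[str, Recipient]
                      ) -> tuple[list[str], dict[str, int]]:
    """Eligible patient ids and the exclusion tally.

    A patient is eligible iff their flag set is empty. Excluded patients are
    counted once, under the first matching flag in the fixed order
    (extracorporeal support, single-lung, re-transplant, delayed extubation
    for other reasons, re-intubation for other reasons).
    """
    eligible: list[str] = []
    tally = {flag: 0 for flag in EXCLUSION_FLAGS}
    for pid, rec in recipients.items():
        if not rec.exclusion_flags:
            eligible.append(pid)
            continue
        for flag in EXCLUSION_FLAGS:
            if flag in rec.exclusion_flags:
                tally[flag] += 1
                break
    return eligible, tally


# --------------------------------------------------------------------------
# writers (round-trip partners of the readers)

def write_records(records: Sequence[VentRecord], path: Path | str) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in RECORD_COLUMNS}
        rows.append(row)
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def write_courses(courses: Sequence[PatientCourse], episodes_path,
                  events_path) -> None:
    epi_rows, ev_rows = [], []
    for c in courses:
        for start, end, interface in c.episodes:
            epi_rows.append({"patient_id": c.patient_id, "start_h": start,
                             "end_h": end, "interface": interface})
        for t in c.extubation_times_h:
            ev_rows.append({"patient_id": c.patient_id,
                            "event_type": "extubation", "time_h": t,
                            "nirs_type": "", "daily_hours": ""})
        for t in c.reintubation_times_h:
            ev_rows.append({"patient_id": c.patient_id,
                            "event_type": "reintubation", "time_h": t,
                            "nirs_type": "", "daily_hours": ""})
        if c.tracheostomy_time_h is not None:
            ev_rows.append({"patient_id": c.patient_id,
                            "event_type": "tracheostomy",
                            "time_h": c.tracheostomy_time_h,
                            "nirs_type": "", "daily_hours": ""})
        if c.first_ps_transition_h is not None:
            ev_rows.append({"patient_id": c.patient_id,
                            "event_type": "ps_transition",
                            "time_h": c.first_ps_transition_h,
                            "nirs_type": "", "daily_hours": ""})
        for s in c.nirs_sessions:
            ev_rows.append({"patient_id": c.patient_id, "event_type": "nirs",
                            "time_h": s.start_h, "nirs_type": s.type,
                            "daily_hours": s.daily_hours})
    pd.DataFrame(epi_rows, columns=EPISODE_COLUMNS).to_csv(
        episodes_path, index=False)
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(
        events_path, index=False)


def write_recipients(recipients: Sequence[Recipient], path) -> None:
    covariate_cols = sorted({k for r in recipients for k in r.covariates})
    rows = []
    for r in recipients:
        row = {"patient_id": r.patient_id, "sex": r.sex,
               "height_m": r.height_m, "weight_kg": r.weight_kg,
               "exclusion_flags": ";".join(sorted(r.exclusion_flags))}
        for c in covariate_cols:
            row[c] = r.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=RECIPIENT_COLUMNS + covariate_cols).to_csv(
        path, index=False)


# --------------------------------------------------------------------------
# key=value configuration files

def load_config(path: Path | str) -> AnalysisConfig:
    """Parse a key=value config file into an AnalysisConfig."""
    cfg = AnalysisConfig()
    valid = {f.name: f.type for f in fields(AnalysisConfig)}
    int_fields = {"cv_repeats", "cv_folds", "seed"}
    bool_fields = {"aggregate_before_derive"}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "index_orientation":
                pairs = dict(p.split(":") for p in value.split(";") if p)
                cfg.index_orientation.update(
                    {k.strip(): v.strip() for k, v in pairs.items()})
            elif key in int_fields:
                setattr(cfg, key, int(value))
            elif key in bool_fields:
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif key in valid:
                setattr(cfg, key, float(value))
            else:
                raise SchemaError(f"{path}:{lineno}: unknown key {key!r}")
    cfg.validate()
    return cfg
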