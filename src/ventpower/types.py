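"""Domain types for the post-transplant ventilation analysis.

The unit conventions used throughout the package:

* time is measured in hours since ICU admission, as reals; intervals are
  half-open ``[start, end)`` so adjacent episodes sum without double counting;
* pressures in cmH2O, volumes in mL, rates in breaths/min, gas tensions in
  mmHg, mechanical power in J/min, power density in cmH2O^2/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_MODES = ("PCV", "PSV")
VALID_INTERFACES = ("ETT", "TRACH")
VALID_SEXES = ("male", "female")
VALID_NIRS_TYPES = ("NHFC", "NIV")

#: fixed attribution order for multi-flag exclusions (first match wins)
EXCLUSION_FLAGS = (
    "postop_ecmo",
    "single_lung",
    "retransplant",
    "delayed_extubation_other",
    "reintubation_other",
)


class InvariantError(ValueError):
    """A record or course violates a declared domain invariant."""


@dataclass(frozen=True)
class VentRecord:
    """One timestamped ventilator observation with its paired blood gas."""

    patient_id: str
    t_h: float
    mode: str
    fio2: float
    rr: float
    vt_ml: float
    ppeak: float
    peep: float
    pao2: float
    paco2: float
    ph: float
    ve_lmin: Optional[float] = None

    def validate(self) -> None:
        if self.mode not in VALID_MODES:
            raise InvariantError(f"unknown ventilation mode {self.mode!r}")
        if self.t_h < 0:
            raise InvariantError("t_h must be non-negative")
        if not (0.21 <= self.fio2 <= 1.0):
            raise InvariantError("fio2 outside [0.21, 1.0]")
        if self.rr <= 0:
            raise InvariantError("respiratory rate must be positive")
        if self.vt_ml <= 0:
            raise InvariantError("tidal volume must be positive")
        if self.peep < 0:
            raise InvariantError("PEEP must be non-negative")
        if self.ppeak <= self.peep:
            raise InvariantError("ppeak must exceed PEEP")
        if self.ve_lmin is not None and self.ve_lmin <= 0:
            raise InvariantError("minute ventilation must be positive")


@dataclass(frozen=True)
class Recipient:
    """Transplant recipient anthropometrics and regression covariates."""

    patient_id: str
    sex: str
    height_m: float
    weight_kg: float
    covariates: dict[str, float] = field(default_factory=dict)
    exclusion_flags: frozenset[str] = frozenset()

    def validate(self) -> None:
        if self.sex not in VALID_SEXES:
            raise InvariantError(f"unknown sex label {self.sex!r}")
        if not (0.5 < self.height_m < 2.5):
            raise InvariantError("height outside plausible range (0.5, 2.5) m")
        if self.weight_kg <= 0:
            raise InvariantError("weight must be positive")
        unknown = set(self.exclusion_flags) - set(EXCLUSION_FLAGS)
        if unknown:
            raise InvariantError(f"unknown exclusion flags {sorted(unknown)}")


@dataclass(frozen=True)
class NirsSession:
    """A non-invasive respiratory support session (NHFC or NIV)."""

    type: str
    start_h: float
    daily_hours: float


@dataclass
class PatientCourse:
    """Episodes and events defining a patient's ventilation course.

    ``episodes`` are invasive ventilation periods (endotracheal tube or
    tracheal cannula), half-open ``[start_h, end_h)`` in hours since ICU
    admission.
    """

    patient_id: str
    episodes: list[tuple[float, float, str]] = field(default_factory=list)
    extubation_times_h: list[float] = field(default_factory=list)
    reintubation_times_h: list[float] = field(default_factory=list)
    tracheostomy_time_h: Optional[float] = None
    first_ps_transition_h: Optional[float] = None
    nirs_sessions: list[NirsSession] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = None
        for start, end, interface in self.episodes:
            if interface not in VALID_INTERFACES:
                raise InvariantError(f"unknown interface {interface!r}")
            if end <= start:
                raise InvariantError("episode end must follow start")
            if prev_end is not None and start < prev_end:
                raise InvariantError("episodes overlap or are unsorted")
            prev_end = end
        ext = sorted(self.extubation_times_h)
        for t in self.reintubation_times_h:
            if not any(e <= t for e in ext):
                raise InvariantError(
                    "reintubation must follow some extubation"
                )


@dataclass(frozen=True)
class CourseSummary:
    """Outcome labels derived from a :class:`PatientCourse`."""

    patient_id: str
    total_invasive_h: float
    scenario: int
    pmv_72: bool
    pmv_96: bool
    pmv_7d: bool
    weaning_readiness_h: Optional[float]
    extubated: bool
    reintubated: bool
    tracheostomy: bool
    nirs: bool


@dataclass
class AnalysisConfig:
    """Knobs of the analysis pipeline.

    ``index_orientation`` maps each index name to the direction in which it
    indicates the positive (prolonged-ventilation) class.
    """

    window_h: float = 36.0
    pmv_threshold_h: float = 72.0
    cv_repeats: int = 2
    cv_folds: int = 5
    alpha: float = 0.05
    seed: int = 0
    #: derive indexes per record then take medians (default) or derive once
    #: from medianed raw variables
    aggregate_before_derive: bool = False
    index_orientation: dict[str, str] = field(default_factory=lambda: dict(
        DEFAULT_ORIENTATION))

    def validate(self) -> None:
        if self.window_h <= 0 or self.pmv_threshold_h <= 0:
            raise InvariantError("window and PMV threshold must be positive")
        if self.cv_folds < 2:
            raise InvariantError("cv_folds must be at least 2")
        if self.cv_repeats < 1:
            raise InvariantError("cv_repeats must be at least 1")
        for name, orient in self.index_orientation.items():
            if orient not in ("higher_is_positive", "lower_is_positive"):
                raise InvariantError(
                    f"bad orientation {orient!r} for index {name!r}")


#: Direction in which each index points toward prolonged ventilation:
#: stiffer, more power-hungry lungs are positive, so compliance and
#: oxygenation point the other way.
DEFAULT_ORIENTATION: dict[str, str] = {
    "mp": "higher_is_positive",
    "pbw_mp": "higher_is_positive",
    "ltcdyn_mp": "higher_is_positive",
    "vr": "higher_is_positive",
    "dp_aw": "higher_is_positive",
    "pf_ratio": "lower_is_positive",
    "ltc_dyn": "lower_is_positive",
}

#: Canonical index column order used in tables and CSV output.
INDEX_NAMES = ("dp_aw", "ltc_dyn", "pf_ratio", "vr", "mp", "pbw_mp",
               "ltcdyn_mp")

#: Raw ventilator/ABG variables aggregated alongside the indexes.
RAW_VARIABLES = ("fio2", "rr", "vt_ml", "ve_lmin", "peep", "ppeak", "pao2",
                 "paco2", "ph")
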