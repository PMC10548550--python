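"""Derived ventilatory indexes.

Everything here operates on a single ventilator observation during
pressure-controlled ventilation plus the recipient's predicted body weight.

The index panel:

* dynamic driving pressure ``dp_aw = Ppeak − PEEP`` (cmH2O);
* dynamic lung-thorax compliance ``ltc_dyn = VT / dp_aw`` (mL/cmH2O), a
  surrogate of ventilated lung volume;
* ``pf_ratio = PaO2 / FiO2`` (mmHg), oxygenation;
* ventilatory ratio ``vr``, measured over ideal CO2 clearance, a dead-space
  surrogate;
* mechanical power ``mp = 0.098 · RR · VT[L] · Ppeak`` (J/min), the
  simplified pressure-controlled form (PEEP + inspiratory driving pressure
  collapses to the peak pressure);
* ``pbw_mp = mp / PBW`` (J/min/kg), power per predicted body weight;
* power density ``ltcdyn_mp = RR · Ppeak · dp_aw`` (cmH2O^2/min), which is
  algebraically mp normalised to compliance after the 0.098 J per
  cmH2O·L conversion — the intensity of mechanical stress per unit of
  ventilated volume.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import VentRecord

#: J per (cmH2O · L): converts pressure-volume products to energy.
JOULES_PER_CMH2O_L = 0.098

#: Ventilatory-ratio normalisation: ideal minute ventilation is
#: 100 mL/kg PBW/min at an ideal PaCO2 of 37.5 mmHg.
VR_IDEAL_VE_ML_PER_KG = 100.0
VR_IDEAL_PACO2_MMHG = 37.5


@dataclass(frozen=True)
class RecordIndexes:
    """The derived index panel for one ventilator observation."""

    dp_aw: float
    ltc_dyn: float
    pf_ratio: float
    vr: float
    mp: float
    pbw_mp: float
    ltcdyn_mp: float


def predicted_body_weight(sex: str, height_m: float) -> float:
    """Predicted body weight (kg) from sex and height (Devine/ARDSNet form).

    male: 50 + 0.91·(height_cm − 152.4); female: 45.5 + 0.91·(height_cm −
    152.4). Returned as computed, even below the 152.4 cm anchor — the caller
    validates plausibility.
    """
    if not (0.5 < height_m < 2.5):
        raise ValueError(f"height {height_m} m outside plausible range")
    base = {"male": 50.0, "female": 45.5}
    try:
        intercept = base[sex]
    except KeyError:
        raise ValueError(f"unknown sex label {sex!r}") from None
    return intercept + 0.91 * (100.0 * height_m - 152.4)


def derive_record_indexes(record: VentRecord, pbw_kg: float) -> RecordIndexes:
    """Compute the full index panel for one record.

    Uses the measured minute ventilation for the ventilatory ratio when
    recorded, otherwise RR·VT.
    """
    if pbw_kg <= 0:
        raise ValueError("predicted body weight must be positive")
    dp_aw = record.ppeak - record.peep
    if dp_aw <= 0:
        raise ValueError("non-physiologic pressures: ppeak must exceed PEEP")
    ltc_dyn = record.vt_ml / dp_aw
    pf_ratio = record.pao2 / record.fio2
    mp = JOULES_PER_CMH2O_L * record.rr * (record.vt_ml / 1000.0) * record.ppeak
    ve_mlmin = (1000.0 * record.ve_lmin if record.ve_lmin is not None
                else record.rr * record.vt_ml)
    vr = (ve_mlmin * record.paco2) / (
        pbw_kg * VR_IDEAL_VE_ML_PER_KG * VR_IDEAL_PACO2_MMHG)
    return RecordIndexes(
        dp_aw=dp_aw,
        ltc_dyn=ltc_dyn,
        pf_ratio=pf_ratio,
        vr=vr,
        mp=mp,
        pbw_mp=mp / pbw_kg,
        ltcdyn_mp=record.rr * record.ppeak * dp_aw,
    )
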