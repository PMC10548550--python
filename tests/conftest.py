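import numpy as np
import pytest

from ventpower.types import PatientCourse, Recipient, VentRecord


@pytest.fixture
def pcv_record():
    """A representative pressure-controlled ventilation observation
    (the all-patient median panel used as a worked example)."""
    return VentRecord(patient_id="p1", t_h=6.0, mode="PCV", fio2=0.39,
                      rr=18.0, vt_ml=402.0, ppeak=23.0, peep=10.0,
                      pao2=104.0, paco2=42.0, ph=7.42)


@pytest.fixture
def simple_course():
    return PatientCourse(patient_id="p1", episodes=[(0.0, 40.0, "ETT")],
                         extubation_times_h=[40.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_record(pid="p", t=6.0, mode="PCV", fio2=0.4, rr=16.0, vt=420.0,
                ppeak=24.0, peep=9.0, pao2=100.0, paco2=41.0, ph=7.41,
                ve=None):
    return VentRecord(patient_id=pid, t_h=t, mode=mode, fio2=fio2, rr=rr,
                      vt_ml=vt, ppeak=ppeak, peep=peep, pao2=pao2,
                      paco2=paco2, ph=ph, ve_lmin=ve)


def make_recipient(pid="p", sex="male", height=1.75, weight=70.0, flags=()):
    return Recipient(patient_id=pid, sex=sex, height_m=height,
                     weight_kg=weight, exclusion_flags=frozenset(flags))
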