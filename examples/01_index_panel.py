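"""Derive the ventilatory index panel for a single observation.

A pressure-controlled ventilation record plus the patient's predicted body
weight yields seven indexes: dynamic driving pressure, dynamic lung-thorax
compliance, P/F ratio, mechanical power, weight- and compliance-normalised
power, and the ventilatory ratio.
"""

from ventpower import VentRecord, derive_record_indexes, predicted_body_weight

record = VentRecord(patient_id="demo", t_h=6.0, mode="PCV", fio2=0.39,
                    rr=18.0, vt_ml=402.0, ppeak=23.0, peep=10.0,
                    pao2=104.0, paco2=42.0, ph=7.42)

pbw = predicted_body_weight("male", height_m=1.76)
panel = derive_record_indexes(record, pbw_kg=pbw)

print(f"predicted body weight : {pbw:8.1f} kg")
print(f"driving pressure      : {panel.dp_aw:8.1f} cmH2O")
print(f"compliance (dynamic)  : {panel.ltc_dyn:8.1f} mL/cmH2O")
print(f"P/F ratio             : {panel.pf_ratio:8.1f} mmHg")
print(f"mechanical power      : {panel.mp:8.2f} J/min")
print(f"power / kg PBW        : {panel.pbw_mp:8.3f} J/min/kg")
print(f"power density         : {panel.ltcdyn_mp:8.0f} cmH2O^2/min")
print(f"ventilatory ratio     : {panel.vr:8.2f}")
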