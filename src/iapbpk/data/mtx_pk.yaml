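# Methotrexate three-compartment disposition (RA patients, 15 mg IV bolus fit).
units:
  cl_renal: mL/h/kg
  vc: mL/kg
  k12: 1/h
  k21: 1/h
  k13: 1/h
  k31: 1/h
  body_weight: kg
cl_renal: 84.9
vc: 64.34
k12: 2.74
k21: 0.895
k13: 0.196
k31: 0.035
body_weight: 70.0
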