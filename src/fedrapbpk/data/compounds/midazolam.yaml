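name: midazolam
mol_weight: 325.8
fu_plasma: 0.032
blood_plasma_ratio: 0.66
ka: 3.0
fa: 1.0
lag_time: 0.1
fg_model: gut_extraction
clint_gut: 4.52
vss: 0.8
v_sac: 0.3
q_sac: 20.0
enzyme_clearances:
  CYP3A4_liver:
    value: 4.5
    unit: uL/min/pmol
    provenance: literature-standard sensitive CYP3A4 probe; calibrated
  HLM_additional:
    value: 40.0
    unit: uL/min/mg
    provenance: minor non-CYP3A4 hepatic share; calibrated
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
provenance: sensitive CYP3A4 index substrate fixture (2 mg single dose)
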