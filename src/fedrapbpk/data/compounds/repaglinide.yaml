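name: repaglinide
mol_weight: 452.6
fu_plasma: 0.015
blood_plasma_ratio: 0.62
ka: 2.0
fa: 1.0
lag_time: 0.1
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.4
v_sac: 0.2
q_sac: 10.0
enzyme_clearances:
  CYP2C8: {value: 31.2, unit: uL/min/pmol, provenance: literature-standard CYP2C8 probe; calibrated}
  CYP3A4_liver: {value: 2.48, unit: uL/min/pmol, provenance: minor CYP3A4 share; calibrated}
  HLM_additional: {value: 272.0, unit: uL/min/mg, provenance: residual hepatic share; calibrated}
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
provenance: CYP2C8 probe substrate fixture (0.25 mg single dose)
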