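name: omeprazole
mol_weight: 345.4
fu_plasma: 0.045
blood_plasma_ratio: 0.6
ka: 2.0
fa: 1.0
lag_time: 0.3
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.25
v_sac: 0.05
q_sac: 5.0
enzyme_clearances:
  CYP2C19: {value: 60.0, unit: uL/min/pmol, provenance: literature-standard CYP2C19 probe; calibrated}
  CYP3A4_liver: {value: 0.6, unit: uL/min/pmol, provenance: minor CYP3A4 share; calibrated}
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
provenance: CYP2C19 probe substrate fixture (20 mg single dose)
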