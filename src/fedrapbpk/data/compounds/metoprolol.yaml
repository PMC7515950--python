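name: metoprolol
mol_weight: 267.4
fu_plasma: 0.88
blood_plasma_ratio: 1.1
ka: 2.0
fa: 0.95
lag_time: 0.2
fg_model: fixed_fg
fixed_fg: 1.0
vss: 4.0
v_sac: 1.0
q_sac: 30.0
enzyme_clearances:
  CYP2D6: {value: 6.0, unit: uL/min/pmol, provenance: literature-standard CYP2D6 probe; calibrated}
  HLM_additional: {value: 0.8, unit: uL/min/mg, provenance: residual hepatic share; calibrated}
cl_renal: 6.0
cl_biliary: 0.0
cl_additional: 0.0
provenance: CYP2D6 probe substrate fixture (100 mg single dose)
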