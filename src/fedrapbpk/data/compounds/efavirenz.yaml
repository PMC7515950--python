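name: efavirenz
mol_weight: 315.7
fu_plasma: 0.01
blood_plasma_ratio: 0.74
ka: 0.6
fa: 0.9
lag_time: 0.5
fg_model: fixed_fg
fixed_fg: 1.0
vss: 3.0
v_sac: 1.0
q_sac: 10.0
enzyme_clearances:
  HLM_additional: {value: 50.0, unit: uL/min/mg, provenance: literature-standard CL; calibrated}
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ind_max: 6.0
    ind_c50: 5.0
    provenance: literature-standard induction; calibrated (moderate inducer class)
  CYP3A4_gut:
    ind_max: 6.0
    ind_c50: 5.0
    provenance: literature-standard induction; calibrated (moderate inducer class)
provenance: moderate CYP3A4 inducer fixture (600 mg QD)
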