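name: rifampin
mol_weight: 822.9
fu_plasma: 0.15
blood_plasma_ratio: 0.9
ka: 1.0
fa: 1.0
lag_time: 0.3
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.6
v_sac: 0.2
q_sac: 10.0
enzyme_clearances:
  HLM_additional: {value: 30.0, unit: uL/min/mg, provenance: literature-standard CL; calibrated}
cl_renal: 1.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ind_max: 16.0
    ind_c50: 0.32
    provenance: literature-standard induction; calibrated (strong inducer class)
  CYP3A4_gut:
    ind_max: 16.0
    ind_c50: 0.32
    provenance: literature-standard induction; calibrated (strong inducer class)
provenance: strong CYP3A4 inducer fixture (600 mg QD)
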