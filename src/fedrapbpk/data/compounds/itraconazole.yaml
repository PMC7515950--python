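name: itraconazole
mol_weight: 705.6
fu_plasma: 0.016
blood_plasma_ratio: 0.58
ka: 0.8
fa: 1.0
lag_time: 0.3
fg_model: fixed_fg
fixed_fg: 1.0
vss: 6.0
v_sac: 2.0
q_sac: 10.0
enzyme_clearances:
  HLM_additional: {value: 120.0, unit: uL/min/mg, provenance: literature-standard CL; calibrated}
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ki_reversible: 0.005
    provenance: literature-standard unbound Ki; calibrated (strong class)
  CYP3A4_gut:
    ki_reversible: 0.005
    provenance: literature-standard unbound Ki; calibrated (strong class)
provenance: strong CYP3A4 inhibitor fixture (200 mg QD)
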