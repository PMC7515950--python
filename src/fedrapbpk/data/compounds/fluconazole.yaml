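name: fluconazole
mol_weight: 306.3
fu_plasma: 0.89
blood_plasma_ratio: 1.0
ka: 1.5
fa: 0.97
lag_time: 0.1
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.7
v_sac: 0.1
q_sac: 5.0
enzyme_clearances:
  HLM_additional:
    value: 0.1
    unit: uL/min/mg
    provenance: minor hepatic share; calibrated
cl_renal: 1.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ki_reversible: 40.0
    provenance: literature-standard unbound Ki; calibrated (moderate class on CYP3A4)
  CYP3A4_gut:
    ki_reversible: 40.0
    provenance: literature-standard unbound Ki; calibrated
  CYP2C19:
    ki_reversible: 2.0
    provenance: literature-standard unbound Ki (dual CYP2C19 inhibition); calibrated
provenance: dual CYP2C19/CYP3A4 inhibitor fixture (400 mg QD)
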