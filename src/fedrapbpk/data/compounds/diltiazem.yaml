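name: diltiazem
mol_weight: 414.5
fu_plasma: 0.2
blood_plasma_ratio: 1.0
ka: 1.5
fa: 0.9
lag_time: 0.2
fg_model: fixed_fg
fixed_fg: 0.9
vss: 3.0
v_sac: 1.0
q_sac: 20.0
enzyme_clearances:
  HLM_additional:
    value: 150.0
    unit: uL/min/mg
    provenance: literature-standard CL; calibrated
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    kinact: 1.4
    ki_app: 2.2
    provenance: literature-standard TDI; calibrated (moderate class)
  CYP3A4_gut:
    kinact: 1.4
    ki_app: 2.2
    provenance: literature-standard TDI; calibrated (moderate class)
provenance: moderate CYP3A4 inhibitor fixture (60 mg TID approximated as 90 mg BID)
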