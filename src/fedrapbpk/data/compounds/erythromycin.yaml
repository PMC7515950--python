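name: erythromycin
mol_weight: 733.9
fu_plasma: 0.16
blood_plasma_ratio: 0.9
ka: 1.0
fa: 0.8
lag_time: 0.2
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.7
v_sac: 0.3
q_sac: 15.0
enzyme_clearances:
  HLM_additional: {value: 60.0, unit: uL/min/mg, provenance: literature-standard CL; calibrated}
cl_renal: 9.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    kinact: 2.2
    ki_app: 12.0
    provenance: literature-standard TDI; calibrated (moderate class)
  CYP3A4_gut:
    kinact: 2.2
    ki_app: 12.0
    provenance: literature-standard TDI; calibrated (moderate class)
provenance: moderate (mechanism-based) CYP3A4 inhibitor fixture (500 mg BID)
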