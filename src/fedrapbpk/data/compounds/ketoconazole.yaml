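name: ketoconazole
mol_weight: 531.4
fu_plasma: 0.015
blood_plasma_ratio: 0.62
ka: 1.5
fa: 1.0
lag_time: 0.2
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.3
v_sac: 0.2
q_sac: 5.0
enzyme_clearances:
  HLM_additional:
    value: 157.0
    unit: uL/min/mg
    provenance: literature-standard CL ~8 L/h; calibrated
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ki_reversible: 0.0215
    provenance: literature-standard unbound Ki; calibrated so the index CYP3A4 probe
      falls in the strong class (>=5x)
  CYP3A4_gut:
    ki_reversible: 0.0215
    provenance: literature-standard unbound Ki; calibrated (strong class)
provenance: strong CYP3A4 inhibitor fixture (200 mg BID reference perpetrator)
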