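name: warfarin
mol_weight: 308.3
fu_plasma: 0.01
blood_plasma_ratio: 0.55
ka: 1.5
fa: 1.0
lag_time: 0.1
fg_model: fixed_fg
fixed_fg: 1.0
vss: 0.11
v_sac: 0.03
q_sac: 1.0
enzyme_clearances:
  CYP2C9: {value: 0.0626, unit: uL/min/pmol, provenance: literature-standard S-warfarin CYP2C9 probe; calibrated}
  HLM_additional: {value: 0.0507, unit: uL/min/mg, provenance: minor non-CYP2C9 hepatic share; calibrated}
cl_renal: 0.0
cl_biliary: 0.0
cl_additional: 0.0
provenance: CYP2C9 probe substrate fixture (15 mg single dose)
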