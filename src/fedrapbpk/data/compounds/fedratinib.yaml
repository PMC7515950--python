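name: fedratinib
mol_weight: 524.68
fu_plasma: 0.05
blood_plasma_ratio: 1.0
ka: 0.6
fa: 0.95
lag_time: 0.3
fg_model: gut_extraction
clint_gut: 3.0
vss: 2.0
v_sac: 3.5
q_sac: 8.0
enzyme_clearances:
  CYP3A4_liver:
    value: 0.658061667585011
    unit: uL/min/pmol
    provenance: retrograde calibration to dose-normalized AUCinf and first-dose fm
      split
  CYP2C19:
    value: 1.119836085849706
    unit: uL/min/pmol
    provenance: retrograde calibration to first-dose fm split
  CYP2D6:
    value: 0.24190164002146855
    unit: uL/min/pmol
    provenance: retrograde calibration to first-dose fm split
  HLM_additional:
    value: 0.3870426240343497
    unit: uL/min/mg
    provenance: retrograde calibration; residual hepatic share
cl_renal: 2.311210468394854
cl_biliary: 1.3411026922790237
cl_additional: 0.0
interactions:
  CYP3A4_liver:
    ki_reversible: 0.85
    kinact: 0.95
    ki_app: 1.0
    ind_max: 1.5
    ind_c50: 1.5
    provenance: calibrated mixed TDI/induction reproducing steady-state fm_CYP3A4
      and accumulation
  CYP2C19:
    ki_reversible: 5.0
    provenance: calibrated weak reversible inhibition (in vitro class)
  CYP2C8:
    ki_reversible: 0.42
    provenance: calibrated to CYP2C8 probe (repaglinide) AUC ratio
  CYP2C9:
    ki_reversible: 50.0
    provenance: calibrated; negligible CYP2C9 inhibition at clinical exposure
transporters:
  OATP1B1: 0.0
provenance: victim model; absorption/distribution from oral PK fit, clearances by
  retrograde calibration
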