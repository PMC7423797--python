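# Packaged default transition registry (published point estimates; the
# DIAG-DOC baseline rate, published rounded to 0.000, is the calibrated
# least-squares value against the REC-DOC monthly-probability column).
model_version: original_2002_2008
p90dm_by_age:
  50-54: 0.028
  55-59: 0.028
  60-64: 0.032
  65-69: 0.032
  70-74: 0.064
  75-79: 0.073
  80-84: 0.114
  85-89: 0.156
  90-95: 0.333
diag_doc:
  family: gompertz
  shape: 0.010
  rate_or_scale: 0.00022883875817988135
  coefficients:
    age_band=55-59: 0.632
    age_band=60-64: 0.591
    age_band=65-69: 1.039
    age_band=70-74: 1.701
    age_band=75-79: 2.159
    age_band=80-84: 2.823
    age_band=85-89: 3.166
    age_band=90-95: 3.315
diag_rec:
  family: gompertz
  shape: -0.016
  rate_or_scale: 0.004
  coefficients:
    lymph_nodes=ge10: -0.519
    pt_stage=pT4: 1.081
    sidedness=left: 0.505
rec_death:
  family: loglogistic
  shape: 1.17
  rate_or_scale: 1390.0
  coefficients:
    age_band=50-54: -3.439
    age_band=55-59: -3.766
    age_band=60-64: -4.094
    age_band=65-69: -4.421
    age_band=70-74: -4.749
    age_band=75-79: -5.076
    age_band=80-84: -5.404
    age_band=85-89: -5.731
    age_band=90-95: -6.059
rec_doc_by_age:
  50-54: 0.000
  55-59: 0.001
  60-64: 0.001
  65-69: 0.001
  70-74: 0.002
  75-79: 0.003
  80-84: 0.004
  85-89: 0.005
  90-95: 0.006
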