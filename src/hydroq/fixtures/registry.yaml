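# Analyte registry.
#
# unit        declared unit of every stored measurement, LOD/LOQ and limit
# lod, loq    instrument detection / quantification limits, in `unit`
# rfd         oral reference dose, always mg/kg/day
# inso_limit  national maximum allowable concentration, in `unit`
# who_limit   international guideline value, in `unit`
#
# Element LODs/LOQs are instrument values in ug/L; for the analytes whose
# declared unit is mg/L they are converted accordingly.
analytes:
  nitrate:
    unit: mg/L
    lod: 0.14
    loq: 0.42
    rfd: 1.6
    inso_limit: 50
    who_limit: 50
  nitrite:
    unit: mg/L
    lod: 0.001
    loq: 0.003
    rfd: 0.1
    inso_limit: 0.1
    who_limit: 3
  Ba:
    unit: ug/L
    lod: 0.098
    loq: 0.293
    rfd: 0.2
    inso_limit: 700
    who_limit: 700
  Be:
    unit: ug/L
    lod: 0.042
    loq: 0.126
    rfd: 0.002
    who_limit: 4
  Ca:
    unit: mg/L
    lod: 0.00054
    loq: 0.001619
  Fe:
    unit: ug/L
    lod: 0.16
    loq: 0.481
    rfd: 0.7
    inso_limit: 300
    who_limit: 300
  K:
    unit: mg/L
    lod: 0.00058
    loq: 0.00174
  Li:
    unit: ug/L
    lod: 0.004
    loq: 0.012
    rfd: 0.028
  Mg:
    unit: mg/L
    lod: 0.001308
    loq: 0.00392
  Mn:
    unit: ug/L
    lod: 0.066
    loq: 0.199
    rfd: 0.14
    inso_limit: 400
    who_limit: 400
  Mo:
    unit: ug/L
    lod: 1.666
    loq: 4.998
    rfd: 0.005
    inso_limit: 70
    who_limit: 70
  Na:
    unit: mg/L
    lod: 0.05132
    loq: 0.15396
    inso_limit: 200
    who_limit: 200
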