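brand,season,analyte,value,sd
BDW1,summer,nitrate,0.89,0.003
BDW1,summer,nitrite,0.01,0.001
BDW1,winter,nitrate,6.91,0.18
BDW1,winter,nitrite,0.001,0.001
BDW2,summer,nitrate,38.87,9.86
BDW2,summer,nitrite,0.02,0.002
BDW2,winter,nitrate,34.03,1.58
BDW2,winter,nitrite,0.002,0.001
BDW3,summer,nitrate,7.52,0.02
BDW3,summer,nitrite,0.07,0.10
BDW3,winter,nitrate,8.16,0.26
BDW3,winter,nitrite,0.002,0.001
BDW4,summer,nitrate,3.60,0.03
BDW4,summer,nitrite,0.04,0
BDW4,winter,nitrate,4.13,0.16
BDW4,winter,nitrite,0.001,0.001
BDW5,summer,nitrate,0.28,0.004
BDW5,summer,nitrite,<0.001,
BDW5,winter,nitrate,1.34,0.02
BDW5,winter,nitrite,<0.001,
BDW6,summer,nitrate,8.42,0.002
BDW6,summer,nitrite,0.08,0
BDW6,winter,nitrate,6.41,0.24
BDW6,winter,nitrite,0.001,0
BDW7,summer,nitrate,5.32,0.003
BDW7,summer,nitrite,0.03,0.001
BDW7,winter,nitrate,5.10,0.22
BDW7,winter,nitrite,<0.001,
BDW8,summer,nitrate,7.10,0.02
BDW8,summer,nitrite,0.04,0.001
BDW8,winter,nitrate,7.76,0.21
BDW8,winter,nitrite,0.001,0.001
BDW9,summer,nitrate,5.78,0.02
BDW9,summer,nitrite,0.04,0.001
BDW9,winter,nitrate,5.36,0.05
BDW9,winter,nitrite,<0.001,
BDW10,summer,nitrate,0.45,0.01
BDW10,summer,nitrite,0.04,0.002
BDW10,winter,nitrate,1.53,0.21
BDW10,winter,nitrite,<0.001,
BDW11,summer,nitrate,0.89,0.004
BDW11,summer,nitrite,0.03,0.001
BDW11,winter,nitrate,1.40,0.01
BDW11,winter,nitrite,<0.001,
BDW12,summer,nitrate,4.00,0.01
BDW12,summer,nitrite,0.02,0.002
BDW12,winter,nitrate,6.04,0.17
BDW12,winter,nitrite,0.001,0.001
BDW13,summer,nitrate,4.89,0.01
BDW13,summer,nitrite,0.13,0.11
BDW13,winter,nitrate,4.36,0.07
BDW13,winter,nitrite,<0.001,
BDW14,summer,nitrate,19.93,0.01
BDW14,summer,nitrite,0.05,0.002
BDW14,winter,nitrate,20.26,0.33
BDW14,winter,nitrite,0.002,0.001
BDW15,summer,nitrate,5.81,0.05
BDW15,summer,nitrite,0.04,0.001
BDW15,winter,nitrate,2.40,0.18
BDW15,winter,nitrite,<0.001,
BMW1,summer,nitrate,2.22,0.002
BMW1,summer,nitrite,<0.001,
BMW1,winter,nitrate,2.21,0.01
BMW1,winter,nitrite,<0.001,
BMW2,summer,nitrate,3.58,0.002
BMW2,summer,nitrite,0.02,0.001
BMW2,winter,nitrate,3.10,0.89
BMW2,winter,nitrite,0.002,0.001
BMW3,summer,nitrate,2.66,0.004
BMW3,summer,nitrite,0.02,0.002
BMW3,winter,nitrate,3.50,0.06
BMW3,winter,nitrite,0.001,0.001
BMW4,summer,nitrate,3.11,0.01
BMW4,summer,nitrite,0.02,0.0003
BMW4,winter,nitrate,4.77,0.10
BMW4,winter,nitrite,<0.001,
BMW5,summer,nitrate,10.75,0.02
BMW5,summer,nitrite,0.03,0.001
BMW5,winter,nitrate,9.96,0.23
BMW5,winter,nitrite,0.002,0.0004
BMW6,summer,nitrate,<0.14,
BMW6,summer,nitrite,<0.001,
BMW6,winter,nitrate,0.48,0.03
BMW6,winter,nitrite,0.001,0.001
BMW7,summer,nitrate,8.44,0.02
BMW7,summer,nitrite,<0.001,
BMW7,winter,nitrate,9.07,0.23
BMW7,winter,nitrite,<0.001,
BMW8,summer,nitrate,9.77,0.02
BMW8,summer,nitrite,0.04,0.001
BMW8,winter,nitrate,4.10,0.12
BMW8,winter,nitrite,0.001,0.0003
BMW9,summer,nitrate,2.23,0.01
BMW9,summer,nitrite,<0.001,
BMW9,winter,nitrate,2.08,0.14
BMW9,winter,nitrite,<0.001,
BMW10,summer,nitrate,3.15,0.05
BMW10,summer,nitrite,0.001,0.001
BMW10,winter,nitrate,3.86,0.13
BMW10,winter,nitrite,0.001,0.001
BMW11,summer,nitrate,1.33,0.001
BMW11,summer,nitrite,0.001,0.001
BMW11,winter,nitrate,2.59,0.07
BMW11,winter,nitrite,0.001,0.001
BMW12,summer,nitrate,1.75,0.02
BMW12,summer,nitrite,<0.001,
BMW12,winter,nitrate,2.98,0.12
BMW12,winter,nitrite,<0.001,
BMW13,summer,nitrate,3.11,0.01
BMW13,summer,nitrite,<0.001,
BMW13,winter,nitrate,4.05,0.06
BMW13,winter,nitrite,<0.001,
BMW14,summer,nitrate,5.32,0.01
BMW14,summer,nitrite,0.01,0
BMW14,winter,nitrate,5.20,0.12
BMW14,winter,nitrite,0.001,0.001
BMW15,summer,nitrate,2.23,0.01
BMW15,summer,nitrite,0.01,0
BMW15,winter,nitrate,2.39,0.17
BMW15,winter,nitrite,<0.001,
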