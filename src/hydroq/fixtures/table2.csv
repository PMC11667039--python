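brand,season,analyte,value,sd
BDW1,pooled,Ba,<0.1,
BDW1,pooled,Be,<0.05,
BDW1,pooled,Ca,0.33,0.01
BDW1,pooled,Fe,1.4,0.3
BDW1,pooled,K,0.02,0.001
BDW1,pooled,Li,<0.004,
BDW1,pooled,Mg,8.87,0.06
BDW1,pooled,Mn,0.2,0.02
BDW1,pooled,Mo,<1.666,
BDW1,pooled,Na,3.68,0.04
BDW2,pooled,Ba,0.9,0.09
BDW2,pooled,Be,<0.05,
BDW2,pooled,Ca,4.16,0.01
BDW2,pooled,Fe,<0.16,
BDW2,pooled,K,0.11,0.0003
BDW2,pooled,Li,<0.004,
BDW2,pooled,Mg,0.68,0.001
BDW2,pooled,Mn,<0.066,
BDW2,pooled,Mo,<1.666,
BDW2,pooled,Na,22.18,0.04
BDW3,pooled,Ba,1.2,0.04
BDW3,pooled,Be,<0.05,
BDW3,pooled,Ca,4.09,0.02
BDW3,pooled,Fe,<0.16,
BDW3,pooled,K,0.11,0.0001
BDW3,pooled,Li,<0.004,
BDW3,pooled,Mg,0.67,0.0001
BDW3,pooled,Mn,<0.066,
BDW3,pooled,Mo,<1.666,
BDW3,pooled,Na,22.06,0.01
BDW4,pooled,Ba,1.7,0.08
BDW4,pooled,Be,<0.05,
BDW4,pooled,Ca,13.09,0.03
BDW4,pooled,Fe,<0.16,
BDW4,pooled,K,0.08,0.0001
BDW4,pooled,Li,0.2,0.01
BDW4,pooled,Mg,4.42,0.02
BDW4,pooled,Mn,<0.066,
BDW4,pooled,Mo,<1.666,
BDW4,pooled,Na,0.93,0.002
BDW5,pooled,Ba,<0.1,
BDW5,pooled,Be,<0.05,
BDW5,pooled,Ca,0.05,0.01
BDW5,pooled,Fe,<0.16,
BDW5,pooled,K,0.23,0.0001
BDW5,pooled,Li,<0.004,
BDW5,pooled,Mg,7.72,0.03
BDW5,pooled,Mn,<0.066,
BDW5,pooled,Mo,<1.666,
BDW5,pooled,Na,10.16,0.03
BDW6,pooled,Ba,10.5,0.01
BDW6,pooled,Be,<0.05,
BDW6,pooled,Ca,12.23,0.01
BDW6,pooled,Fe,<0.16,
BDW6,pooled,K,0.14,0.003
BDW6,pooled,Li,1.3,0.03
BDW6,pooled,Mg,3.00,0.006
BDW6,pooled,Mn,<0.066,
BDW6,pooled,Mo,<1.666,
BDW6,pooled,Na,2.85,0.01
BDW7,pooled,Ba,10.2,0.05
BDW7,pooled,Be,<0.05,
BDW7,pooled,Ca,9.04,0.01
BDW7,pooled,Fe,<0.16,
BDW7,pooled,K,0.10,0.0002
BDW7,pooled,Li,0.2,0.04
BDW7,pooled,Mg,5.08,0.006
BDW7,pooled,Mn,<0.066,
BDW7,pooled,Mo,<1.666,
BDW7,pooled,Na,10.89,0.01
BDW8,pooled,Ba,58.6,0.51
BDW8,pooled,Be,<0.05,
BDW8,pooled,Ca,17.18,0.08
BDW8,pooled,Fe,<0.16,
BDW8,pooled,K,0.12,0.001
BDW8,pooled,Li,1.8,0.04
BDW8,pooled,Mg,6.71,0.01
BDW8,pooled,Mn,<0.066,
BDW8,pooled,Mo,<1.666,
BDW8,pooled,Na,7.93,0.04
BDW9,pooled,Ba,1.8,0.04
BDW9,pooled,Be,<0.05,
BDW9,pooled,Ca,6.78,0.04
BDW9,pooled,Fe,<0.16,
BDW9,pooled,K,0.15,0.0001
BDW9,pooled,Li,5.7,0.06
BDW9,pooled,Mg,4.47,0.02
BDW9,pooled,Mn,<0.066,
BDW9,pooled,Mo,<1.666,
BDW9,pooled,Na,21.18,0.06
BDW10,pooled,Ba,15.3,0.02
BDW10,pooled,Be,<0.05,
BDW10,pooled,Ca,10.46,0.01
BDW10,pooled,Fe,0.0,0.04
BDW10,pooled,K,0.13,0.0001
BDW10,pooled,Li,2.1,0.07
BDW10,pooled,Mg,4.74,0.01
BDW10,pooled,Mn,0.1,0.01
BDW10,pooled,Mo,<1.666,
BDW10,pooled,Na,23.32,0.01
BDW11,pooled,Ba,5.7,0.01
BDW11,pooled,Be,<0.05,
BDW11,pooled,Ca,9.17,0.07
BDW11,pooled,Fe,<0.16,
BDW11,pooled,K,0.15,0.0004
BDW11,pooled,Li,1.5,0.07
BDW11,pooled,Mg,5.52,0.04
BDW11,pooled,Mn,<0.066,
BDW11,pooled,Mo,<1.666,
BDW11,pooled,Na,4.69,0.01
BDW12,pooled,Ba,23.05,0.38
BDW12,pooled,Be,<0.05,
BDW12,pooled,Ca,6.03,0.02
BDW12,pooled,Fe,<0.16,
BDW12,pooled,K,0.23,0.0002
BDW12,pooled,Li,2.8,0.01
BDW12,pooled,Mg,7.48,0.01
BDW12,pooled,Mn,<0.066,
BDW12,pooled,Mo,<1.666,
BDW12,pooled,Na,17.92,0.11
BDW13,pooled,Ba,1.38,0.07
BDW13,pooled,Be,<0.05,
BDW13,pooled,Ca,6.01,0.01
BDW13,pooled,Fe,<0.16,
BDW13,pooled,K,0.14,0.0003
BDW13,pooled,Li,5.2,0.03
BDW13,pooled,Mg,4.01,0.001
BDW13,pooled,Mn,<0.066,
BDW13,pooled,Mo,<1.666,
BDW13,pooled,Na,19.34,0.16
BDW14,pooled,Ba,14.55,0.0
BDW14,pooled,Be,<0.05,
BDW14,pooled,Ca,16.42,0.02
BDW14,pooled,Fe,<0.16,
BDW14,pooled,K,0.09,0.0002
BDW14,pooled,Li,4.4,0.02
BDW14,pooled,Mg,8.08,0.0004
BDW14,pooled,Mn,0.36,0.01
BDW14,pooled,Mo,<1.666,
BDW14,pooled,Na,5.63,0.02
BDW15,pooled,Ba,2.05,0.03
BDW15,pooled,Be,<0.05,
BDW15,pooled,Ca,3.09,0.03
BDW15,pooled,Fe,<0.16,
BDW15,pooled,K,0.03,0.0007
BDW15,pooled,Li,0.0,0.02
BDW15,pooled,Mg,2.96,0.01
BDW15,pooled,Mn,<0.066,
BDW15,pooled,Mo,<1.666,
BDW15,pooled,Na,12.07,0.08
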