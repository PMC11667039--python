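brand,season,analyte,value,sd
BMW1,pooled,Ba,<0.1,
BMW1,pooled,Be,<0.05,
BMW1,pooled,Ca,3.28,0.01
BMW1,pooled,Fe,<0.16,
BMW1,pooled,K,0.36,0.001
BMW1,pooled,Li,6.35,0.001
BMW1,pooled,Mg,1.24,0.01
BMW1,pooled,Mn,<0.066,
BMW1,pooled,Mo,<1.666,
BMW1,pooled,Na,3.15,0.012
BMW2,pooled,Ba,0.49,0.04
BMW2,pooled,Be,<0.05,
BMW2,pooled,Ca,9.55,0.04
BMW2,pooled,Fe,<0.16,
BMW2,pooled,K,0.07,0.0001
BMW2,pooled,Li,1.1,0.005
BMW2,pooled,Mg,3.64,0.01
BMW2,pooled,Mn,<0.066,
BMW2,pooled,Mo,<1.666,
BMW2,pooled,Na,0.89,0.01
BMW3,pooled,Ba,<0.1,
BMW3,pooled,Be,<0.05,
BMW3,pooled,Ca,8.38,0.05
BMW3,pooled,Fe,<0.16,
BMW3,pooled,K,0.04,0.0001
BMW3,pooled,Li,<0.004,
BMW3,pooled,Mg,1.86,0.01
BMW3,pooled,Mn,<0.066,
BMW3,pooled,Mo,<1.666,
BMW3,pooled,Na,2.92,0.01
BMW4,pooled,Ba,12.03,0.12
BMW4,pooled,Be,<0.05,
BMW4,pooled,Ca,25.95,0.13
BMW4,pooled,Fe,<0.16,
BMW4,pooled,K,0.25,0.0004
BMW4,pooled,Li,5.69,0.04
BMW4,pooled,Mg,6.77,0.02
BMW4,pooled,Mn,<0.066,
BMW4,pooled,Mo,<1.666,
BMW4,pooled,Na,3.56,0.003
BMW5,pooled,Ba,<0.1,
BMW5,pooled,Be,<0.05,
BMW5,pooled,Ca,3.36,0.02
BMW5,pooled,Fe,<0.16,
BMW5,pooled,K,0.37,0.001
BMW5,pooled,Li,6.42,0.04
BMW5,pooled,Mg,1.26,0.01
BMW5,pooled,Mn,<0.066,
BMW5,pooled,Mo,<1.666,
BMW5,pooled,Na,3.17,0.03
BMW6,pooled,Ba,10.76,0.03
BMW6,pooled,Be,<0.05,
BMW6,pooled,Ca,23.02,0.04
BMW6,pooled,Fe,<0.16,
BMW6,pooled,K,0.12,0.0002
BMW6,pooled,Li,1.97,0.02
BMW6,pooled,Mg,9.34,0.13
BMW6,pooled,Mn,<0.066,
BMW6,pooled,Mo,<1.666,
BMW6,pooled,Na,3.91,0.04
BMW7,pooled,Ba,11.16,0.13
BMW7,pooled,Be,<0.05,
BMW7,pooled,Ca,18.92,0.09
BMW7,pooled,Fe,<0.16,
BMW7,pooled,K,0.17,0.0002
BMW7,pooled,Li,4.16,0.02
BMW7,pooled,Mg,4.03,0.01
BMW7,pooled,Mn,<0.066,
BMW7,pooled,Mo,<1.666,
BMW7,pooled,Na,12.32,0.05
BMW8,pooled,Ba,6.46,0.01
BMW8,pooled,Be,<0.05,
BMW8,pooled,Ca,14.04,0.04
BMW8,pooled,Fe,<0.16,
BMW8,pooled,K,0.10,0.0004
BMW8,pooled,Li,<0.004,
BMW8,pooled,Mg,2.00,0.004
BMW8,pooled,Mn,<0.066,
BMW8,pooled,Mo,<1.666,
BMW8,pooled,Na,2.68,0.004
BMW9,pooled,Ba,<0.1,
BMW9,pooled,Be,<0.05,
BMW9,pooled,Ca,3.35,0.003
BMW9,pooled,Fe,<0.16,
BMW9,pooled,K,0.37,0.0001
BMW9,pooled,Li,6.38,0.02
BMW9,pooled,Mg,1.24,0.01
BMW9,pooled,Mn,<0.066,
BMW9,pooled,Mo,<1.666,
BMW9,pooled,Na,3.19,0.02
BMW10,pooled,Ba,55.9,0.35
BMW10,pooled,Be,<0.05,
BMW10,pooled,Ca,9.62,0.01
BMW10,pooled,Fe,<0.16,
BMW10,pooled,K,0.09,0.0003
BMW10,pooled,Li,<0.004,
BMW10,pooled,Mg,6.63,0.002
BMW10,pooled,Mn,<0.066,
BMW10,pooled,Mo,<1.666,
BMW10,pooled,Na,1.22,0.001
BMW11,pooled,Ba,10.9,0.02
BMW11,pooled,Be,<0.05,
BMW11,pooled,Ca,10.90,0.10
BMW11,pooled,Fe,<0.16,
BMW11,pooled,K,0.05,0.0003
BMW11,pooled,Li,<0.004,
BMW11,pooled,Mg,5.39,0.01
BMW11,pooled,Mn,<0.066,
BMW11,pooled,Mo,<1.666,
BMW11,pooled,Na,0.61,0.01
BMW12,pooled,Ba,13.9,0.01
BMW12,pooled,Be,<0.05,
BMW12,pooled,Ca,11.02,0.01
BMW12,pooled,Fe,<0.16,
BMW12,pooled,K,0.04,0.0004
BMW12,pooled,Li,<0.004,
BMW12,pooled,Mg,5.52,0.003
BMW12,pooled,Mn,<0.066,
BMW12,pooled,Mo,<1.666,
BMW12,pooled,Na,0.55,0.002
BMW13,pooled,Ba,31.1,0.23
BMW13,pooled,Be,<0.05,
BMW13,pooled,Ca,25.64,0.06
BMW13,pooled,Fe,<0.16,
BMW13,pooled,K,0.09,0.0001
BMW13,pooled,Li,1.7,0.01
BMW13,pooled,Mg,3.36,0.02
BMW13,pooled,Mn,<0.066,
BMW13,pooled,Mo,<1.666,
BMW13,pooled,Na,4.99,0.001
BMW14,pooled,Ba,4.4,0.03
BMW14,pooled,Be,<0.05,
BMW14,pooled,Ca,13.55,0.02
BMW14,pooled,Fe,<0.16,
BMW14,pooled,K,0.06,0.0001
BMW14,pooled,Li,1.2,0.01
BMW14,pooled,Mg,2.71,0.001
BMW14,pooled,Mn,<0.066,
BMW14,pooled,Mo,<1.666,
BMW14,pooled,Na,1.06,0.004
BMW15,pooled,Ba,<0.1,
BMW15,pooled,Be,<0.05,
BMW15,pooled,Ca,3.35,0.01
BMW15,pooled,Fe,<0.16,
BMW15,pooled,K,0.37,0.001
BMW15,pooled,Li,6.3,0.01
BMW15,pooled,Mg,1.25,0.01
BMW15,pooled,Mn,<0.066,
BMW15,pooled,Mo,<1.666,
BMW15,pooled,Na,3.13,0.002
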