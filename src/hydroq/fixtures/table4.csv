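brand,analyte,value
BDW1,nitrate,2.4
BDW1,nitrite,NA
BDW1,Ca,<1
BDW1,K,0.12
BDW1,Mg,2.5
BDW1,Na,1.3
BDW2,nitrate,39
BDW2,nitrite,<0.02
BDW2,Ca,36
BDW2,K,NA
BDW2,Mg,12.5
BDW2,Na,12
BDW3,nitrate,NA
BDW3,nitrite,NA
BDW3,Ca,50
BDW3,K,NA
BDW3,Mg,12
BDW3,Na,NA
BDW4,nitrate,3.5
BDW4,nitrite,0.01
BDW4,Ca,38
BDW4,K,NA
BDW4,Mg,7.8
BDW4,Na,1
BDW5,nitrate,<1
BDW5,nitrite,NA
BDW5,Ca,<5
BDW5,K,1
BDW5,Mg,13
BDW5,Na,16
BDW6,nitrate,0.4
BDW6,nitrite,0
BDW6,Ca,20
BDW6,K,0.8
BDW6,Mg,10
BDW6,Na,1
BDW7,nitrate,<2
BDW7,nitrite,0
BDW7,Ca,35
BDW7,K,0.4
BDW7,Mg,8
BDW7,Na,9
BDW8,nitrate,NA
BDW8,nitrite,NA
BDW8,Ca,50
BDW8,K,NA
BDW8,Mg,12
BDW8,Na,NA
BDW9,nitrate,2.3
BDW9,nitrite,<0.05
BDW9,Ca,11.5
BDW9,K,NA
BDW9,Mg,4.3
BDW9,Na,16.7
BDW10,nitrate,3.5
BDW10,nitrite,0.01
BDW10,Ca,24.8
BDW10,K,2
BDW10,Mg,10
BDW10,Na,10.7
BDW11,nitrate,1.3
BDW11,nitrite,0.005
BDW11,Ca,32
BDW11,K,0.7
BDW11,Mg,7.68
BDW11,Na,14
BDW12,nitrate,1
BDW12,nitrite,0
BDW12,Ca,20
BDW12,K,NA
BDW12,Mg,15
BDW12,Na,8
BDW13,nitrate,2.3
BDW13,nitrite,<0.05
BDW13,Ca,11.5
BDW13,K,NA
BDW13,Mg,4.3
BDW13,Na,16.7
BDW14,nitrate,15
BDW14,nitrite,0
BDW14,Ca,50
BDW14,K,NA
BDW14,Mg,15
BDW14,Na,9
BDW15,nitrate,0
BDW15,nitrite,0
BDW15,Ca,29
BDW15,K,0.5
BDW15,Mg,1.5
BDW15,Na,32
BMW1,nitrate,2.5
BMW1,nitrite,<0.005
BMW1,Ca,9.6
BMW1,K,NA
BMW1,Mg,2.2
BMW1,Na,4.6
BMW2,nitrate,<0.8
BMW2,nitrite,<0.004
BMW2,Ca,32.8
BMW2,K,NA
BMW2,Mg,6.4
BMW2,Na,NA
BMW3,nitrate,7.1
BMW3,nitrite,0.014
BMW3,Ca,28.3
BMW3,K,NA
BMW3,Mg,2.85
BMW3,Na,7
BMW4,nitrate,2
BMW4,nitrite,0.01
BMW4,Ca,50
BMW4,K,1.36
BMW4,Mg,6.25
BMW4,Na,17
BMW5,nitrate,NA
BMW5,nitrite,NA
BMW5,Ca,12
BMW5,K,NA
BMW5,Mg,2.1
BMW5,Na,8
BMW6,nitrate,0.74
BMW6,nitrite,0.02
BMW6,Ca,69.5
BMW6,K,0.64
BMW6,Mg,NA
BMW6,Na,7
BMW7,nitrate,2.88
BMW7,nitrite,NA
BMW7,Ca,53
BMW7,K,NA
BMW7,Mg,9
BMW7,Na,11
BMW8,nitrate,0.005
BMW8,nitrite,0.003
BMW8,Ca,48
BMW8,K,NA
BMW8,Mg,10.20
BMW8,Na,2.76
BMW9,nitrate,NA
BMW9,nitrite,NA
BMW9,Ca,10
BMW9,K,NA
BMW9,Mg,1.81
BMW9,Na,NA
BMW10,nitrate,0.9
BMW10,nitrite,0
BMW10,Ca,28
BMW10,K,NA
BMW10,Mg,12.9
BMW10,Na,2.3
BMW11,nitrate,0.7
BMW11,nitrite,0.01
BMW11,Ca,30
BMW11,K,NA
BMW11,Mg,8
BMW11,Na,6
BMW12,nitrate,0.7
BMW12,nitrite,0.01
BMW12,Ca,20
BMW12,K,NA
BMW12,Mg,0
BMW12,Na,6
BMW13,nitrate,0.8
BMW13,nitrite,0.003
BMW13,Ca,81.6
BMW13,K,1.04
BMW13,Mg,5.1
BMW13,Na,4.41
BMW14,nitrate,5
BMW14,nitrite,0
BMW14,Ca,90
BMW14,K,0.15
BMW14,Mg,33.1
BMW14,Na,0.51
BMW15,nitrate,0.5
BMW15,nitrite,0
BMW15,Ca,10
BMW15,K,NA
BMW15,Mg,0.3
BMW15,Na,4.5
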