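variable,quotient
X07,1.0126
X14,1.0055
X08,1.0044
X12,1.0025
X19,1.0007
X20,0.9999
X10,0.9986
X13,0.9982
X03,0.9965
X01,0.9956
X18,0.9956
X06,0.9913
X05,0.9894
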