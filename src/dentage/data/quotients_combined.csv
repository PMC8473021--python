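variable,quotient
X04,1.0126
X02,1.0125
X15,1.0122
X18,1.0057
X11,1.0051
X12,1.0051
X20,1.0024
X14,1.0010
X03,1.0010
X16,1.0010
X08,1.0009
X19,1.0008
X17,1.0004
X10,1.0004
SEX,1.0003
X06,1.0002
X01,1.0002
X07,1.0001
X09,1.0001
X21,1.0001
X05,1.0000
X13,0.9999
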