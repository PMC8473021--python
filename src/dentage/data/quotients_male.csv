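variable,quotient
X10,1.0544
X14,1.0354
X08,1.0254
X12,1.0216
X07,1.0214
X18,1.0162
X13,1.0127
X15,1.0094
X11,1.0037
X04,1.0007
X02,1.0007
X17,0.9958
X19,0.9934
X03,0.9900
X05,0.9821
X16,0.9806
X06,0.9253
X01,0.9193
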