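label,class
A01,A
A01a,A
A01b,A
A02,A
A03,A
A04,A
A05,A
A06,A
A07,A
B01,B
B03,B
B04,B
B05,B
B06,B
B09,B
B10,B
B11,B
B12,B
B13,B
B17,B
B18,B
C01,C
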