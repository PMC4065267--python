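haplotype,labels
S01,B10;B11
S02,A01;A03
S03,B06
S04,B01;B13
S05,A05
S06,B04;C01
S07,A01;A02
S08,B03
S09,A06;A07
S10,B05
S11,B09;B12
S12,B17;B18
S13,A04
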