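individual,A01a,A01b,A02,A03,A04,A05,A06,A07,B01,B03,B04,B05,B06,B09,B10,B11,B12,B13,B17,B18,C01
1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,1,0,0,0,0
2,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,1,0,0,0,0
3,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0
4,1,0,0,1,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0
5,0,1,0,1,0,0,0,0,0,0,0,0,0,1,0,0,1,0,0,0,0
6,1,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
7,1,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
8,0,0,0,0,0,0,1,1,0,0,0,0,1,0,0,0,0,0,0,0,0
9,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,1,1,0
10,0,0,0,0,0,0,0,0,1,0,0,0,1,0,0,0,0,1,0,0,0
11,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,1,0,0,1
12,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0
13,0,0,0,0,0,1,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1
14,0,0,0,0,0,1,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1
15,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
16,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
17,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1
18,1,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1
19,0,0,0,0,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0
20,0,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0
21,0,0,0,0,1,0,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0
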