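individual,hap1_labels,hap2_labels,status
1,B09;B12,B10;B11,heterozygous
2,B09;B12,B10;B11,heterozygous
3,B10;B11,B10;B11,confirmed_homozygote
4,A01;A03,B10;B11,heterozygous
5,A01;A03,B09;B12,heterozygous
6,A01;A02,A01;A03,heterozygous
7,A01;A03,B06,heterozygous
8,A06;A07,B06,heterozygous
9,B06,B17;B18,heterozygous
10,B01;B13,B06,heterozygous
11,B01;B13,B04;C01,heterozygous
12,A05,B01;B13,heterozygous
13,A05,B04;C01,heterozygous
14,A05,B04;C01,heterozygous
15,A05,B05,heterozygous
16,A05,B05,heterozygous
17,B04;C01,B04;C01,confirmed_homozygote
18,A01;A02,B04;C01,heterozygous
19,B03,B06,heterozygous
20,B03,B05,heterozygous
21,A04,B01;B13,heterozygous
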