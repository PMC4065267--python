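cohort_id,collection,parent1,parent2,n,labels,count
3x6,F1o,3,6,7,A01;A02;B10;B11,4
3x6,F1o,3,6,7,A01;A03;B10;B11,3
3x7,F1o,3,7,13,A01;A03;B10;B11,7
3x7,F1o,3,7,13,B06;B10;B11,6
8x4,F1o,8,4,5,A01;A03;A06;A07,2
8x4,F1o,8,4,5,A06;A07;B10;B11,1
8x4,F1o,8,4,5,A01;A03;B06,2
8x6,F1o,8,6,7,A01;A03;A06;A07,1
8x6,F1o,8,6,7,A01;A02;B06,3
8x6,F1o,8,6,7,A01;A03;B06,3
9x4,F1o,9,4,21,A01;A03,4
9x4,F1o,9,4,21,B10;B11,1
9x4,F1o,9,4,21,A01;A03;B06,10
9x4,F1o,9,4,21,B06;B10;B11,6
9x6,F1o,9,6,7,A01;A02,3
9x6,F1o,9,6,7,A01;A03,2
9x6,F1o,9,6,7,A01;A02;B06,2
10x4,F1o,10,4,6,A01;A03;B01,1
10x4,F1o,10,4,6,B01;B10;B11,4
10x4,F1o,10,4,6,A01;A03;B06,1
10x6,F1o,10,6,16,A01;A02;B01,2
10x6,F1o,10,6,16,A01;A03;B01,6
10x6,F1o,10,6,16,A01;A02;B06,6
10x6,F1o,10,6,16,A01;A03;B06,2
4x20,F1c,4,20,14,A01;A03;B03,3
4x20,F1c,4,20,14,A01;A03;B05,2
4x20,F1c,4,20,14,B03;B10;B11,4
4x20,F1c,4,20,14,B05;B10;B11,5
12x8,F1c,12,8,30,A05;A06;A07,7
12x8,F1c,12,8,30,A05;B06,6
12x8,F1c,12,8,30,A06;A07;B01,6
12x8,F1c,12,8,30,B01;B06,11
17x18,F1c,17,18,30,A01;A02;B04;C01,13
17x18,F1c,17,18,30,B04;C01,17
18x1,F1c,18,1,50,A01;A02;B09;B12,11
18x1,F1c,18,1,50,A01;A02;B10;B11,15
18x1,F1c,18,1,50,B04;B09;B12;C01,9
18x1,F1c,18,1,50,B04;B10;B11;C01,15
21x8,F1c,21,8,14,A06;A07;B01,4
21x8,F1c,21,8,14,A04;A06;A07,1
21x8,F1c,21,8,14,B01;B06,5
21x8,F1c,21,8,14,A04;B06,4
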