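source_score,equated_score
0,0
1,1
2,3
3,4
4,5
5,7
6,8
7,10
8,11
9,13
10,15
11,16
12,18
13,20
14,22
15,24
16,27
17,30
18,33
19,37
20,42
21,63
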