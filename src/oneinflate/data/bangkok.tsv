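count	frequency
1	2176
2	1600
3	1278
4	976
5	748
6	570
7	455
8	368
9	281
10	254
11	188
12	138
13	99
14	67
15	44
16	34
17	17
18	3
19	3
20	2
21	1
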