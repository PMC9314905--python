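count	frequency
1	1206
2	474
3	198
4	95
5	29
6	19
7	5
8	2
9	0
10	1
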