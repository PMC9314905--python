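count	frequency
1	541
2	169
3	95
4	37
5	21
6	23
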