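time	status
0.8	1
1.0	0
2.7	0
3.1	1
5.4	1
7.0	0
9.2	1
12.1	0
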