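site	genotypes
1	B, C1, C2
3	C2, D
5	C1, C2, D
6	A, B
7	B, C1, C2, D, E, G
11	C2, E, G
15	B, C2
30	C2, D
57	C, D
58	C, E
64	C, E
67	C2, E
70	C, E
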