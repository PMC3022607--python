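genotype	bands
A	200/170/155/125
B	312/225/<100
C1	181/140/125/112
C2	181/125/140/112
D	187/156/148/130
E	156/142/125/108/<100
F	162/149/136/126/<100
G	155/136/125/106/<100
H	204/174/155/149/124
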