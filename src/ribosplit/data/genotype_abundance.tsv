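genotype	n_specimens	frequency_pct	map_sites
A	4	1.3	6
B	25	8.2	1, 4, 6, 7, 13, 15, 33, 37, 38, 73, 74
C1	11	3.6	1, 3
C2	170	56.3	1, 2, 3, 7, 14, 16, 17, 18, 26, 28, 30, 36, 40, 42, 43, 44, 45, 46, 47, 50, 52, 55, 57, 58, 59, 61, 62, 63, 64, 66, 68, 69, 70, 71, 72
D	24	7.9	3, 5, 7, 18, 19, 30, 32, 57, 75
E	38	12.1	7, 8, 10, 11, 12, 20, 34, 39, 42, 49, 50, 58, 64, 67, 70, 76
F	8	2.6	23, 31, 53
G	17	5.6	7, 9, 11, 27, 29
H	5	2.6	26, 30
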