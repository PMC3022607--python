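map_site	year_site	latitude	longitude	n_specimens
1	1993/2	-3.82139	141.4575	12
2	1993/3	-3.3483	141.3457	1
3	1993/5	-3.41618	141.2422	12
4	1993/6	-4.14264	141.2604	2
5	1993/8	-4.34685	141.6606	1
6	1993/10	-3.97867	141.654	12
7	1993/14	-3.38709	141.586	14
8	1993/17	-3.10225	141.2592	2
9	1993/22	-3.81907	141.0429	1
10	1993/23	-3.8498	142.061	3
11	1993/27	-3.83852	142.3608	10
12	1993/32	-4.27391	142.1417	1
13	1993/42	-3.96715	141.2027	2
14	1993/43	-3.93283	142.2043	10
15	1993/45	-3.82202	141.8232	2
16	1993/47	-3.20563	142.1934	1
17	1993/49	-2.83613	146.226	1
18	1993/53	-3.04691	141.6254	5
19	1993/54	-2.98728	141.4841	4
20	1993/99	-3.87055	143.7083	5
21	1994/52	-7.94629	145.9866	1
22	1994/53	-7.86491	145.6693	1
23	1994/62	-7.94385	146.1063	1
24	1995/86	-4.55097	145.1288	0 (4)
25	1992/68	-6.10497	141.3719	0 (1)
26	1992/63	-5.99314	141.1222	4
27	1992/79	-5.73255	141.9284	3
28	1992/71	-5.79571	141.0625	3
29	1992/70	-5.11318	141.1066	4
30	1992/62	-6.31728	141.0249	12
31	1992/28	-8.14579	141.983	6
32	1992/65	-6.1281	141.2741	1
33	1994/63	-7.58825	143.687	1
34	1995/1	-5.29123	145.7411	1
35	1995/118	-5.21938	145.5545	1
36	1995/18	-3.89964	143.9252	1
37	1995/34	-4.63884	143.6642	1
38	1995/35	-4.62367	143.6128	1
39	1995/74	-4.61152	145.4955	4
40	1995/75	-4.86588	145.6067	1
41	1995/78	-4.3246	145.0033	1
42	1995/90	-4.60145	145.4423	3
43	1995/98	-4.20768	144.448955	5
44	1995/111	-4.71896	144.4958	3
45	1995/114	-4.98081	144.9456	4
46	1995/120	-5.12045	145.4077	2
47	1995/123	-5.46082	145.2102	1
48	1995/125	-5.56242	146.1766	0 (1)
49	1995/130	-4.78272	145.6285	3
50	1995/134	-5.59874	146.2804	1
51	1995/138	-5.11788	145.4628	2
52	1995/157	-5.07679	144.7181	1
53	1997/122	-10.1185	148.296	1
54	1997/128	-10.1015	148.4675	1
55	1998/171	-9.62046	149.4318	1
56	1998/183	-8.81208	148.4748	1
57	1993/76	-4.06985	143.2562	9 (2)
58	1995/137	-5.23905	145.4598	11 (1)
59	1995/4	-5.29396	145.7483	10 (2)
60	1995/7	-5.28947	145.7628	11 (1)
61	1995/15	-5.4142	145.7264	11 (1)
62	1995/77	-4.91868	145.7815	12
63	1995/88	-4.87637	145.0901	1
64	1995/89	-4.6723	145.5873	12
65	1995/81	-4.56498	145.3099	10 (2)
66	1995/86	-4.55097	145.1288	1
67	1995/106	-4.6723	145.5873	12
68	1995/132	-5.07245	145.0517	4
69	1995/136	-5.48847	145.7741	3 (1)
70	1996/75	-6.57615	146.8209	11
71	1995/158	-5.33051	144.8912	1
72	1996/136	-5.53449	145.3597	1
73	1993/54	-2.98728	141.4841	2
74	1993/70	-4.61974	143.4462	3
75	1993/94	-3.76457	143.1519	1
76	1993/98	-3.78299	143.3662	1
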