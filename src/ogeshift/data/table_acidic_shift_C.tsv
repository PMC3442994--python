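index	sequence	mass_nl	mass_l	difference	frac_nl	frac_l	flags
1	SKFDNLYGCR	1258.56	1547.79	289.22	11	10
2	QFNGLVDVYKK	1292.69	1743.02	450.33	11	9,10	$
3	KGPLIVYGTEGAK	1331.73	1765.06	433.33	11	9
4	YLQPQESGWKPK	1459.80	1893.06	433.26	11	9,10
5	GVQQVLQNYK	1175.61	1464.84	289.23	12	10
6	KQFVIDVLHPGR	1407.81	1697.01	289.20	12	10
7	ASALIQHEWRPK	1434.76	1723.98	289.22	12	10
8	LSEPYKGIGDCFKR	1668.82	2102.14	433.33	12	9,10
9	GVLPQNQPFVVK	1324.74	1613.96	289.22	12	10,11
10	INWLTNPVHK	1220.65	1509.88	289.22	12	10
11	IAGFSTHLMK	1103.57	1392.79	289.22	12	10
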