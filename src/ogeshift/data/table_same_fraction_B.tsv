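index	sequence	mass_nl	mass_l	difference	frac_nl	frac_l	flags
1	MFDAGLYEHCR	1397.58	1542.69	145.12	4	4	*
2	EAFPGDVFYLHSR	1536.75	1681.85	145.09	4	5	*
3	TLHGLQPPESSGIFNEK	1852.93	2142.14	289.22	4	4	*
4	ATFDCLMK	984.49	1273.65	289.16	5	5	*
5	GIPYLNTYDGR	1267.67	1412.73	145.06	5,6	5,6	*
6	GFGFVTFANEK	1215.62	1504.80	289.18	2,6	6
7	GKDFAELIASGR	1262.67	1551.87	289.21	6	6
8	AALNDFDRFK	1195.60	1484.81	289.21	6	6
9	EAQWAHAQR	1095.52	1240.63	145.11	8	8	*
10	SRFFHSTGQR	1221.54	1366.71	145.17	8	8	*
11	AGDFFHSAQSR	1221.56	1366.66	145.11	8	8	*
12	ASALIQHDWSR	1282.63	1427.75	145.12	8	8	*
13	AHGGFSVFAGVGER	1389.69	1534.79	145.10	8	8
14	VGPFHNPSETYR	1402.65	1547.77	145.12	8	8
15	GVDKEHVMLLAAR	1437.77	1726.99	289.22	8	8
16	EVHFLPFNPVDKR	1596.85	1886.05	289.20	8	8
17	EIHFLPFNPVDKR	1610.87	1900.07	289.20	8	8
18	ALYHDLNAYR	1234.61	1379.72	145.11	8	8
19	AGVKPHELVF	1095.61	1384.82	289.21	8	8
20	LAWHSAGTFDSK	1318.61	1607.84	289.23	8	8	*
21	YDTVHGQWK	1132.52	1421.74	289.22	8	8
22	NGGANFVAPGYTK	1294.54	1583.84	289.31	10	10
23	AASFNIIPSSTGAAK	1433.76	1722.96	289.21	10	10
24	FVTAVVGFGK	1023.57	1312.79	289.21	10	10
25	AGQYNFLIR	1080.58	1225.68	145.10	12	12
26	AYGGVLSGGAVR	1105.59	1250.70	145.10	12	12
27	GFQTSYYNR	1134.50	1279.62	145.12	11,12	12
28	VLNTGSPISVPVGR	1394.76	1539.90	145.13	12	12
29	SSSVFIPHGPGAVR	1409.73	1554.85	145.12	12	12
30	LVSAHSSQQIYTR	1488.75	1633.88	145.13	12	12
31	GGGHTSQIYAIR	1258.65	1403.75	145.11	12	12
32	HGSLGFLPR	982.53	1127.64	145.12	12	12
33	GGQLIYGGPLGR	1186.63	1331.76	145.12	12	12
34	AGGAYTLNTASAVTVR	1550.79	1695.91	145.12	12	12
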