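index	sequence	mass_nl	mass_l	difference	frac_nl	frac_l	flags
1	ECADLWPR	1045.46	1190.57	145.11	1	3,4
2	AYLEDFYR	1075.50	1220.61	145.11	1	3,4
3	EQMGYTFDALK	1301.58	1590.81	289.23	1	3,4
4	TMADEGVVALWR	1346.65	1491.77	145.12	1,2	3,4
5	ECSGVEPQLWAR	1430.66	1575.77	145.11	1	3,4
6	NQIDEIVLVGGSTR	1499.78	1644.90	145.13	1	3,4
7	LAEMPADSGYPAYLAAR	1794.84	1939.97	145.13	1	3,4
8	ELEFYMK	958.46	1247.66	289.20	1	3
9	IPSAVGYQPTLSTDLGGLQER	2201.13	2346.24	145.11	1	3,4
10	AQIWDTAGQER	1273.59	1418.71	145.12	1	3,4
11	AGGECLTFDQLALR	1549.77	1694.87	145.10	1	3,4
12	VDFAYSFFEK	1251.61	1540.79	289.18	1	3
13	IFDKPEDFIAER	1478.74	1767.95	289.22	1	3,4
14	GLFTSDQILFTDTR	1612.79	1757.92	145.13	1	3,4
15	TTPSYVAFTDSER	1472.66	1617.79	145.13	1	3,4
16	LDTGNFSWGSEAVTR	1638.76	1783.87	145.11	1	3,4
17	LWQVPETLPAEVVGK	1664.93	1954.13	289.19	2	3,4
18	QLDAHIEEQFGGGR	1555.73	1700.85	145.11	2	3,4
19	GFGFVTFAEEK	1230.61	1519.80	289.19	2	3,4
20	AFLVEEQK	962.51	1251.72	289.21	2	3,4
21	IFEGEALLR	1046.59	1191.69	145.10	2	3,4
22	ISGLIYEETR	1179.61	1324.72	145.11	2	3,4
23	TTAEEGVVALWR	1330.71	1475.80	145.09	2	3,4
24	LLIQNQDEMIK	1343.72	1632.92	289.21	2	3,4
25	IQDKEGIPPDQQR	1522.77	1811.99	289.22	2	3,4
26	TMVYPEAGFELQR	1539.74	1684.85	145.10	2	3,4
27	EQDVSLGANKFPER	1588.77	1878.00	289.22	2	3,4
28	GQGGIQQLLAAEQEAQR	1795.93	1941.03	145.10	2	3,4
29	QYAVFDEK	981.46	1287.68	306.22	2	3,4	$
30	QLDSHIEEQFGGGR	1554.71	1716.84	162.13	2	3,4	$
31	FDVGVKEIEGWTAR	1605.84	1895.03	289.19	2	3,4
32	HFEVDLSAFR	1219.61	1364.71	145.10	3	4
33	CALVYGQMNEPPGAR	1661.78	1806.87	145.10	4	6
34	NAVVTVPAYFNDSQR	1679.84	1824.94	145.10	4	5,6
35	QPTELELAQAFHQGK	1695.85	1985.07	289.22	4	5
36	TALTYVDNNDGSWHR	1747.80	1892.90	145.10	4	5
37	QQFPLALYQVDK	1448.78	1737.98	289.20	4	5,6
38	ADGFAGVFPEHK	1273.60	1562.82	289.22	4	5
39	SLEGLQANVQR	1213.63	1358.75	145.13	4	6
40	TFDNVYYK	1048.47	1337.70	289.23	4	5
41	MLSPLILGDEHYQTAR	1842.96	1988.04	145.08	4	5
42	SSFDAFQQILK	1282.67	1571.87	289.20	4	5
43	SSDFLMYGIK	1159.57	1448.77	289.20	4	5
44	SSMDAFQQILK	1282.67	1571.83	289.17	5	5
45	FTQANSEVSALLGR	1491.77	1636.88	145.11	5	6
46	STLVWEVR	988.56	1133.64	145.08	5	6
47	IFLENVIR	1002.62	1147.70	145.07	5	6
48	FFCEFCGK	1093.48	1382.65	289.17	5	6
49	EVAGFAPYEKR	1265.65	1554.85	289.20	5,6	6
50	SFGPAVIFNNEK	1321.70	1610.88	289.18	5	6
51	VALINYGPEYGR	1350.75	1495.80	145.06	5	6
52	YIAPEQVPVK	1142.63	1431.85	289.21	5	5,6
53	VEPLVNMGQITR	1355.72	1500.83	145.12	5	6
54	AYEPILLLGR	1143.67	1288.77	145.10	5	6
55	LVGEYGLR	905.51	1050.61	145.10	5	6
56	EALGGLPLYQR	1215.66	1360.77	145.11	5	6
57	ADAFLLVGTQPR	1286.70	1431.81	145.10	5	6,7
58	HGWEYVVK	1016.51	1305.72	289.21	6	8
59	FVIGGPHGDAGLTGR	1452.75	1597.86	145.10	7	8
60	LVNVFTIGK	989.60	1278.80	289.20	7	9,10
61	THAVVEPFVIATNR	1552.86	1697.95	145.09	7	8,9
62	SVHEPMQTGLK	1225.62	1514.82	289.21	7	8
63	SVVYALSPFQQK	1365.74	1654.94	289.20	7	10
64	YGGGANFVHDGYNK	1497.61	1786.88	289.27	7	8
65	TALTYIDGNGNWHR	1616.76	1761.88	145.12	8	9
66	AHLQDYIQTHYTAPR	1812.89	1958.00	145.11	8	9
67	NYTNAFQALYR	1359.66	1504.77	145.11	10	12
68	TLHPNWSPAAIK	1333.72	1622.93	289.21	10	11
69	FHQYQVVGR	1132.56	1277.69	145.13	11	12
70	FQSLGVAFYR	1186.64	1331.72	145.08	11	12
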