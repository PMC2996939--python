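agi	n_sites	n_ps	n_pt	n_py	length	go6139
AT5G52040.1	22	19	1	2	357	True
AT2G29210.1	16	13	1	2	879	True
AT2G37340.1	13	13	0	0	291	True
AT5G64200.1	13	13	0	0	304	True
AT2G43680.1	13	11	2	0	669	False
AT3G55460.1	13	11	0	2	263	True
AT1G35580.1	12	10	2	0	552	False
AT3G25500.1	12	12	0	0	1052	False
AT3G63400.1	12	11	1	0	571	True
AT5G47690.1	12	10	2	0	1606	False
AT3G23900.1	11	11	0	0	988	False
AT2G18960.1	11	5	4	2	950	False
AT2G20960.1	11	4	7	0	749	False
AT3G53500.1	10	9	0	1	244	True
AT4G33240.1	10	8	2	0	1758	False
AT5G01400.1	10	7	3	0	1468	True
AT1G31870.1	10	10	0	0	562	False
AT5G47430.1	10	9	0	1	893	False
AT4G32420.1	9	8	0	1	838	False
AT5G10470.1	9	9	0	0	1274	False
AT4G02510.1	9	8	1	0	1504	False
AT4G31160.1	9	7	2	0	1847	False
AT3G26935.1	9	6	2	1	444	False
AT5G47910.1	9	9	0	0	922	False
AT5G61150.1	9	9	0	0	626	False
AT5G43310.1	9	5	4	0	1238	False
AT5G40450.1	9	8	1	0	2890	False
AT3G13570.1	9	8	1	0	263	True
AT3G61860.1	9	8	0	1	265	True
AT1G48920.1	9	8	1	0	558	False
AT1G19870.1	9	9	0	0	795	False
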