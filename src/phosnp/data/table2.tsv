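agi	n_significant_windows	windows
AT4G07523.1	4	5(6), 6(4), 4(7), 5(1)
AT4G33240.1	4	4(1538), 4(1545), 4(1557), 5(1543)
AT1G53165.1	3	4(442), 4(439), 5(441)
AT2G46170.1	3	4(22), 5(28), 4(29)
AT3G04650.1	3	4(4), 5(3), 4(1)
AT1G35580.1	2	4(66), 4(44)
AT3G18180.1	2	4(67), 4(69)
AT1G08680.1	1	4(191)
AT1G29220.1	1	4(81)
AT1G55310.1	1	4(5)
AT1G70130.1	1	4(281)
AT1G73200.1	1	4(313)
AT2G26730.1	1	4(632)
AT2G35880.1	1	4(109)
AT2G41705.1	1	4(61)
AT2G46495.1	1	4(402)
AT3G27960.1	1	4(574)
AT3G29310.1	1	4(325)
AT3G29390.1	1	4(512)
AT3G48530.1	1	4(14)
AT3G55460.1	1	4(176)
AT3G58940.1	1	4(113)
AT4G14605.1	1	4(290)
AT4G31580.1	1	4(170)
AT4G32250.1	1	4(22)
AT5G02240.1	1	4(235)
AT5G14890.1	1	4(60)
AT5G52040.1	1	4(342)
AT5G64200.1	1	4(274)
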