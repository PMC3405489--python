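library_id	raw	adapter_matched	length_filtered	low_complexity_redundant	low_complexity_nonredundant	contaminant_redundant	contaminant_nonredundant	genome_matched_redundant	genome_matched_nonredundant
BF1	2842653	2332661	1592671	1582689	356161	1335567	333478	797297	207233
BF2	2553116	2124140	1570583	1560824	370103	1401892	351620	817438	220223
BF3	2641037	2184480	1646360	1635958	387915	1466005	368373	853043	235873
F1	2523898	1819981	1180424	1173273	215571	858130	194546	368958	78332
F2	2898014	2361457	1389585	1381108	233414	1040918	214222	630870	115644
F3	3613383	2923242	1768783	1757830	320484	1362239	297258	700729	143030
GF1	2696289	2170904	1354915	1346476	307349	1200810	289976	774146	190043
GF2	3722325	2848155	1962881	1950819	429497	1570664	405303	928251	248399
GF3	2952035	2254276	1327544	1319295	308967	1145330	291401	609728	168939
GL1	2357377	1707677	1072569	1065997	241873	870779	220909	481523	122824
GL2	2304406	1729282	1080322	1073580	253835	929602	234995	460632	125267
GL3	1822754	1345521	745352	740785	207198	616318	190449	338168	111111
O1	3704334	2907197	1811057	1799817	327514	1384994	302970	890186	182703
O2	1896816	1509747	1068609	1061991	226499	911190	208620	624084	129672
O3	2235893	1753142	1286833	1278775	282053	1093002	263673	696601	162637
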