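# Mass-spectrometry detections of A. thaliana nucleoporins from purified
# root-protoplast nuclei, three technical replicates.
# Columns: protein, accession, emPAI per replicate, s.d. per replicate,
# presence = replicates-detected / replicates-total.
protein	accession	empai_1	empai_2	empai_3	sd_1	sd_2	sd_3	presence
ALADIN	AAAS_ARATH	0.4000	0.3560	0.1987	0.1267	0.1746	0.0782	3/3
NUP50C	Q93ZH3_ARATH	0.0914	0.0000	0.0000	0.0033	0.0000	0.0000	1/3
HOS1	HOS1_ARATH	0.5453	0.7713	0.6147	0.0792	0.0665	0.0990	3/3
NUP205	A0A1P8BGZ1_ARATH	0.5220	0.5757	0.6167	0.1031	0.1561	0.1902	3/3
GP210	GP210_ARATH	0.9063	1.3200	1.0507	0.3410	0.0300	0.1028	3/3
NUP35	NUP35_ARATH	0.1230	0.1827	0.0000	0.0046	0.0809	0.0000	2/3
NUP43	NUP43_ARATH	0.1127	0.4867	0.2793	0.1115	0.5187	0.0588	3/3
NUP50B	NU50B_ARATH	0.0603	0.0000	0.0000	0.1045	0.0000	0.0000	1/3
NUP54	NUP54_ARATH	0.1773	0.5193	0.0000	0.0601	0.1638	0.0000	2/3
NUP58	NUP58_ARATH	0.1572	0.0867	0.0182	0.0782	0.0891	0.0315	3/3
NUP62	NUP62_ARATH	0.3720	0.6040	0.0821	0.1005	0.1459	0.0037	3/3
NUP82	F4K465_ARATH	0.0171	0.0589	0.0361	0.0296	0.0585	0.0016	3/3
NUP85	NUP85_ARATH	0.6697	1.0183	0.6583	0.1230	0.2886	0.2657	3/3
NUP88	NUP88_ARATH	0.1689	0.1087	0.1398	0.0645	0.0586	0.0632	3/3
NUP93A	NP93A_ARATH	0.7823	0.6067	0.3477	0.0926	0.3361	0.1736	3/3
NUP93B	NU93B_ARATH	0.1094	0.0654	0.0948	0.0777	0.0277	0.0839	3/3
NUP96	NUP96_ARATH	0.1643	0.3200	0.1400	0.0609	0.1416	0.0320	3/3
NUP98A	NU98A_ARATH	0.0542	0.0764	0.0189	0.0235	0.0568	0.0164	3/3
NUP107	NU107_ARATH	0.1710	0.2847	0.2340	0.0879	0.0081	0.0187	3/3
NUP133	NU133_ARATH	0.2017	0.3237	0.2163	0.0736	0.1061	0.0097	3/3
NUP155	NU155_ARATH	0.6537	0.7207	0.4023	0.0672	0.1554	0.0668	3/3
NUP160	NU160_ARATH	0.2690	0.2323	0.3240	0.0501	0.1061	0.0901	3/3
NUP214	NP214_ARATH	0.0000	0.0080	0.0155	0.0000	0.0139	0.0160	2/3
NUA	NUA_ARATH	0.4960	0.6093	0.4250	0.1025	0.1793	0.0267	3/3
NUP188	F4JUG3_ARATH	0.1155	0.1032	0.0177	0.0360	0.0560	0.0069	3/3
NDC1	Q8LAF4_ARATH	0.2993	0.1712	0.1066	0.0589	0.0878	0.0930	3/3
GLE1	GLE1_ARATH	0.0000	0.0000	0.0135	0.0000	0.0000	0.0233	1/3
RAE1	RAE1_ARATH	0.4657	1.0457	0.1330	0.0692	0.9646	0.0454	3/3
SEH1	SEH1_ARATH	0.4093	0.6237	0.2433	0.1678	0.2010	0.0663	3/3
SEC13A	SC13A_ARATH	0.5030	0.1993	0.1254	0.1828	0.0907	0.0595	3/3
SEC13B	SC13B_ARATH	1.7567	0.9040	0.6103	0.5021	0.2272	0.1463	3/3
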