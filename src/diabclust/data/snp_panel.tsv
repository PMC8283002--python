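rsid	gene	chrom	bp	risk_allele	other_allele	raf
rs7903146	TCF7L2	10	114758349	T	C	0.28
rs163184	KCNQ1	11	2847069	G	T	0.50
rs10923931	NOTCH2	1	120517959	T	G	0.13
rs6795735	ADAMTS9	3	64705365	C	T	0.59
rs11634397	ZFAND6	15	80432222	G	A	0.66
rs16927668	PTPRD	9	8369533	T	C	0.18
rs4299828	ZFAND3	6	38177667	A	G	0.81
rs459193	ANKRD55	5	55806751	G	A	0.72
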