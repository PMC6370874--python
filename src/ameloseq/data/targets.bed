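chr1	210	496	HRAS
chr1	584	641	HRAS
chr1	821	909	KRAS
chr1	988	1139	KRAS
chr1	1206	1315	KRAS
chr1	1571	1760	NRAS
chr1	1840	1964	NRAS
chr1	2213	2476	TP53
chr1	2534	2609	TP53
chr1	2692	2747	TP53
chr1	2952	3230	PTEN
chr1	3426	3611	GATA3
chr1	3655	3723	GATA3
chr2	217	462	BRAF
chr2	552	946	BRAF
chr2	1033	1672	BRAF
chr2	1774	2499	BRAF
chr2	2632	2834	SMO
chr2	2965	4037	SMO
chr2	4088	4557	SMO
chr2	4722	5042	EGFR
chr2	5101	5184	EGFR
chr2	5403	5628	MYC
chr2	5703	5836	MYC
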