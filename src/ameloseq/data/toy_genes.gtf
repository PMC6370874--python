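chr1	ameloseq	transcript	221	631	.	+	.	gene_id "HRAS"; transcript_id "HRAS-201"; gene_name "HRAS";
chr1	ameloseq	exon	221	486	.	+	.	gene_id "HRAS"; transcript_id "HRAS-201"; gene_name "HRAS";
chr1	ameloseq	exon	595	631	.	+	.	gene_id "HRAS"; transcript_id "HRAS-201"; gene_name "HRAS";
chr1	ameloseq	CDS	221	486	.	+	.	gene_id "HRAS"; transcript_id "HRAS-201"; gene_name "HRAS";
chr1	ameloseq	CDS	595	631	.	+	.	gene_id "HRAS"; transcript_id "HRAS-201"; gene_name "HRAS";
chr1	ameloseq	transcript	832	1305	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	exon	832	899	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	exon	999	1129	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	exon	1217	1305	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	CDS	832	899	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	CDS	999	1129	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	CDS	1217	1305	.	+	.	gene_id "KRAS"; transcript_id "KRAS-201"; gene_name "KRAS";
chr1	ameloseq	transcript	1582	1954	.	-	.	gene_id "NRAS"; transcript_id "NRAS-201"; gene_name "NRAS";
chr1	ameloseq	exon	1582	1750	.	-	.	gene_id "NRAS"; transcript_id "NRAS-201"; gene_name "NRAS";
chr1	ameloseq	exon	1851	1954	.	-	.	gene_id "NRAS"; transcript_id "NRAS-201"; gene_name "NRAS";
chr1	ameloseq	CDS	1582	1750	.	-	.	gene_id "NRAS"; transcript_id "NRAS-201"; gene_name "NRAS";
chr1	ameloseq	CDS	1851	1954	.	-	.	gene_id "NRAS"; transcript_id "NRAS-201"; gene_name "NRAS";
chr1	ameloseq	transcript	2224	2737	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	exon	2224	2466	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	exon	2545	2599	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	exon	2703	2737	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	CDS	2224	2466	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	CDS	2545	2599	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	CDS	2703	2737	.	-	.	gene_id "TP53"; transcript_id "TP53-201"; gene_name "TP53";
chr1	ameloseq	transcript	2963	3220	.	+	.	gene_id "PTEN"; transcript_id "PTEN-201"; gene_name "PTEN";
chr1	ameloseq	exon	2963	3220	.	+	.	gene_id "PTEN"; transcript_id "PTEN-201"; gene_name "PTEN";
chr1	ameloseq	CDS	2963	3220	.	+	.	gene_id "PTEN"; transcript_id "PTEN-201"; gene_name "PTEN";
chr1	ameloseq	transcript	3437	3713	.	+	.	gene_id "GATA3"; transcript_id "GATA3-201"; gene_name "GATA3";
chr1	ameloseq	exon	3437	3601	.	+	.	gene_id "GATA3"; transcript_id "GATA3-201"; gene_name "GATA3";
chr1	ameloseq	exon	3666	3713	.	+	.	gene_id "GATA3"; transcript_id "GATA3-201"; gene_name "GATA3";
chr1	ameloseq	CDS	3437	3601	.	+	.	gene_id "GATA3"; transcript_id "GATA3-201"; gene_name "GATA3";
chr1	ameloseq	CDS	3666	3713	.	+	.	gene_id "GATA3"; transcript_id "GATA3-201"; gene_name "GATA3";
chr2	ameloseq	transcript	228	2489	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	exon	228	452	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	exon	563	936	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	exon	1044	1662	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	exon	1785	2489	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	CDS	228	452	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	CDS	563	936	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	CDS	1044	1662	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	CDS	1785	2489	.	-	.	gene_id "BRAF"; transcript_id "BRAF-201"; gene_name "BRAF";
chr2	ameloseq	transcript	2643	4547	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	exon	2643	2824	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	exon	2976	4027	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	exon	4099	4547	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	CDS	2643	2824	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	CDS	2976	4027	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	CDS	4099	4547	.	+	.	gene_id "SMO"; transcript_id "SMO-201"; gene_name "SMO";
chr2	ameloseq	transcript	4733	5174	.	+	.	gene_id "EGFR"; transcript_id "EGFR-201"; gene_name "EGFR";
chr2	ameloseq	exon	4733	5032	.	+	.	gene_id "EGFR"; transcript_id "EGFR-201"; gene_name "EGFR";
chr2	ameloseq	exon	5112	5174	.	+	.	gene_id "EGFR"; transcript_id "EGFR-201"; gene_name "EGFR";
chr2	ameloseq	CDS	4733	5032	.	+	.	gene_id "EGFR"; transcript_id "EGFR-201"; gene_name "EGFR";
chr2	ameloseq	CDS	5112	5174	.	+	.	gene_id "EGFR"; transcript_id "EGFR-201"; gene_name "EGFR";
chr2	ameloseq	transcript	5414	5826	.	-	.	gene_id "MYC"; transcript_id "MYC-201"; gene_name "MYC";
chr2	ameloseq	exon	5414	5618	.	-	.	gene_id "MYC"; transcript_id "MYC-201"; gene_name "MYC";
chr2	ameloseq	exon	5714	5826	.	-	.	gene_id "MYC"; transcript_id "MYC-201"; gene_name "MYC";
chr2	ameloseq	CDS	5414	5618	.	-	.	gene_id "MYC"; transcript_id "MYC-201"; gene_name "MYC";
chr2	ameloseq	CDS	5714	5826	.	-	.	gene_id "MYC"; transcript_id "MYC-201"; gene_name "MYC";
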