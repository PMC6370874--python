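# Demo cancer-gene list: canine orthologs of recurrently mutated human cancer
# genes. The study design restricts tumor-only SNV calls to such a list; the
# full working list (union of curated cancer-gene panels, 597 genes) is not
# redistributable here, so this demo subset covers the genes relevant to the
# toy genome plus common drivers. One symbol per line; '#' starts a comment.
HRAS
KRAS
NRAS
BRAF
SMO
FGFR4
TP53
EGFR
PTEN
MYC
GATA3
PIK3CA
CTNNB1
APC
CDKN2A
RB1
NOTCH1
FBXW7
IDH1
AKT1
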