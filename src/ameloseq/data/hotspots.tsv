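# Demo human cancer-hotspot catalog (curated recurrent somatic mutation sites).
# Positions are HUMAN protein coordinates; they are transferred to canine
# coordinates by ortholog protein alignment at run time. alt_aas is a
# comma-separated set of permitted substitutions; empty = any non-reference.
gene	human_pos	ref_aa	alt_aas
HRAS	12	G	D,V,S,C,A
HRAS	13	G	R,V,D,C
HRAS	61	Q	R,K,L,H
KRAS	12	G	D,V,C,A,S,R
KRAS	13	G	D,C
KRAS	61	Q	R,K,L,H
NRAS	61	Q	R,K,L,H
BRAF	600	V	E,K
SMO	535	W	L
SMO	473	D	H
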