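# Methods

## Scope and data model

`ameloseq` starts from called SNVs (VCF 4.x); alignment and primary variant
calling are upstream and out of scope, as are indel consequences and
multi-isoform annotation. VCF and protein positions are 1-based; all
interval arithmetic (BED targets, exons, segments) is 0-based half-open.
Multi-allelic records are split per ALT; indel alleles are skipped with a
logged count. Depth evidence is taken from FORMAT `DP`/`AD`, falling back to
freebayes-style `RO`/`AO`, then mpileup-style INFO `DP4`; a record with no
usable depth fields is kept and flagged `no_evidence` (it then fails the
evidence stage with that reason) rather than silently dropped, because the
caller dialect behind a cohort VCF is rarely uniform.

## Consequence classification

Each SNV is classified against one transcript model per gene (no isoform
arbitration) into a closed class set: missense, stop_gain, splice_donor,
splice_acceptor, synonymous, stop_loss, start_loss, intronic, noncoding,
intergenic. Splice donor/acceptor sites are exactly the 2 intronic bases
flanking each exon boundary (canonical GT/AG positions). Minus-strand
transcripts are handled by complementing alleles before codon lookup; the
standard nuclear codon table is used. Precedence choices at codon
boundaries: a change in the terminal codon that destroys the stop is
stop_loss; any non-synonymous change in the initiation codon — including
one introducing a stop — is start_loss. "High consequence" (what the
cascade retains) is the closed set {missense, stop_gain, splice_donor,
splice_acceptor}; start_loss and stop_loss are deliberately excluded.
The classifier is validated exhaustively against an independent oracle that
rebuilds the mutant genome, re-translates the entire CDS and diffs the two
proteins, over every possible SNV on random transcripts of both strands.

Our GTF dialect writes CDS features that include the stop codon, so
`protein_length = CDS_length/3 − 1`; the bundled reader assumes the same.

## Hotspot orthology transfer

Human hotspot catalogs (gene, residue position, reference residue,
permitted substitutions; an empty substitution set means any non-reference
change) are transferred to canine coordinates via global protein alignment
of the ortholog pair. The aligner is a three-state Gotoh dynamic program,
BLOSUM62 scores, affine gaps costing `11 + (k−1)·1` — standard protein
defaults, configurable per call. It is implemented in-package so traceback
ties break in a fixed order (diagonal > up > left; end state match > up >
left), making the residue map bit-reproducible; the test suite checks score
optimality against an independent library aligner. A hotspot whose human
residue aligns to a gap is reported absent; a canine residue differing from
the catalog's reference is flagged but not fatal (true inter-species
reference differences exist). Which canine gene is the ortholog is input
(paired protein FASTAs), not inferred.

A variant matches a hotspot when it is missense (or stop-gain where the
catalog permits `*`), its protein position equals the mapped canine
position, its reference residue matches the catalog, and its substitution
is permitted.

## Filtering cascade and rescue

Stages run in the order gene list → known-SNP exclusion → evidence →
consequence → hotspot. Stages are conjunctive, so the survivor set is
order-invariant; per-stage rejection counts in trace reports are not, and
follow that order. Both evidence-band endpoints are inclusive (depth ≥ 20;
0.20 ≤ VAF ≤ 0.50). VAF above the band fails: the band's upper edge is what
excludes germline heterozygotes in a tumor-only design. Known-SNP exclusion
is an exact site+allele match against a supplied VCF.

The rescue emulates targeted manual inspection of hotspot loci. It operates
on the genomic positions of mapped hotspot codons and promotes a variant to
`rescued` iff it was rejected at the evidence stage with all earlier stages
passing, sits at a hotspot locus, has VAF in [0.05, 0.50] and ≥ 4
alt-supporting reads. The floor and read count are this package's declared
proxy for manual review: low enough to admit a purity-0.22 clonal driver
(VAF ≈ 11%) with margin, high enough to exclude FFPE-artifact-level noise;
both are configurable. Rescue never applies above the band (a high-VAF
failure looks germline, not low-purity somatic) and never demotes a call.

## Read-depth copy number

Tumor-only cohorts have no matched normals, so each sample is normalized
against the rest of the cohort: a bin's signal is
`log2(d_i / median(d)) − median_panel(log2(p_i / median(p)))`, cancelling
both library size and shared per-target capture efficiency. Bins with zero
sample depth or zero panel median are masked. Segmentation recursively
finds, within each block, the internal window whose mean contrast against
the rest of the block is largest, and cuts when the contrast exceeds both
an absolute floor (0.1 in log2) and a noise-scaled t-like statistic
(threshold 5), with per-bin noise estimated robustly from the MAD of first
differences; windows touching a block edge reduce to plain binary splits.
Testing windows rather than single cut points keeps short internal events
detectable — a single top-level split dilutes a 30-bin event inside a
300-bin profile below any sensible threshold. Minimum segment size is 5
bins; adjacent segments with means within 0.1 are re-merged. The window
scan is O(n²) per block, intended for profiles of hundreds to a few
thousand bins. A segment is copy-neutral when |log2| < 0.3; a profile is
"flat" when ≥ 95% of its bins lie in copy-neutral segments. All thresholds
are configurable; there is no GC correction (the synthetic data carries no
GC bias; a correction would slot in before normalization).

## Synthetic cohorts

The generator emulates the variant-call content of a tumor-only FFPE exome
study on a packaged toy genome (10 multi-exon genes on 2 contigs, both
strands, canonical GT/AG introns; hotspot codons placed so canonical driver
substitutions are single-base changes; the toy human BRAF ortholog carries
a 5-residue insertion upstream of the kinase hotspot so human 600 ↔ canine
595). Per case:

* **Driver**: mutually exclusive assignment, HRAS-Q61R with probability
  0.63 and BRAF-V595E with 0.08 (the emulated cohort's rates); single-clone
  diploid model, VAF = purity/2 with purity ~ U(0.2, 0.9), read support
  Binomial(depth, purity/2).
* **Germline**: 30 heterozygous (Binomial(depth, 0.5)) and 15 homozygous
  (Binomial(depth, 0.98)) SNPs per case, drawn from a shared 150-site
  catalogued universe that is also emitted as the known-SNP VCF.
* **FFPE artifacts**: Poisson(20) C>T calls per case with VAF ~
  Beta(1.5, 40) (mean ≈ 3.6%) — a declared assumption for cytosine
  deamination, not a measured spectrum.
* **Depth**: negative binomial, mean 116, shape 10.

Randomness: one RNG stream per case derived from (seed, case index), so
per-case output is stable under cohort resizing; fixed seed and config give
byte-identical files. Every emitted record is traceable to exactly one
truth category.

The CNA profile simulator is separate: 300-bin grids, shared log-normal
per-bin capture efficiencies (sd 0.3) that panel normalization must cancel,
near-Poisson depth noise (negative binomial shape 200 — counting noise
dominates once shared capture bias is modelled explicitly), and single
gain/loss events (default 30 bins at |log2| ≈ 0.585, i.e. 3 copies).

What the simulation does **not** model: read-level data (FASTQ/BAM),
subclonality (a hook would replace purity/2 with cancer-cell-fraction ×
purity/2), GC bias, strand artifacts, mappability, and copy-number change
at driver loci (driver VAF assumes a copy-neutral locus). Passing the
end-to-end tests therefore shows the cascade's logic is correct under the
stated statistical model, not that it is robust to every FFPE failure mode
of real libraries.

## Validation harness and problem sizes

`end_to_end_recovery` simulates a cohort, runs the cascade plus rescue per
case, and scores case-level sensitivity/specificity and the recovered
MAPK-driver frequency against the configured truth, with a central 95%
binomial interval around the true rate. At the defaults, expected
sensitivity is slightly below 1: a purity-0.9 driver has E[VAF] = 0.45 and
a ~10–15% chance of sampling above the 0.50 band edge, where rescue
deliberately does not apply. The test suite and acceptance script use
200-case cohorts for recovery, 16-profile cohorts (one aberrant) for the
flatness call, and 25 replicate single-event profiles for breakpoint
recovery; these sizes give stable statistics at interactive runtimes.
Because the recovery criterion is itself a 95% interval, roughly 1 seed in
20 fails it with a perfectly functioning pipeline (the truth assignment is
a binomial draw); the fixed-seed tests pass, and failures at other seeds
trace to the assignment draw, not detection.

## Known limitations

* One transcript per gene; no severity ranking across isoforms.
* Hotspot catalog and cancer-gene list ship as small documented demo
  fixtures, swappable by flag/config; they are not a curated release of any
  external database.
* Segments can bridge contig boundaries if a cohort's bin grid mixes
  contigs with similar means; the bundled simulators use single-contig
  grids.
* Rescue is locus-based (as manual inspection is): a non-driver variant at
  a hotspot locus passing the rescue thresholds would be promoted; in
  practice the gene-list and known-SNP stages still apply.
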