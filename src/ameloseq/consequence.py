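"""SNV consequence classification against transcript models.

Replaces an external variant-effect annotator for the pipeline's needs: each
SNV is classified into one of a closed set of classes, and coding changes are
reported as protein changes like ``Q61R``. Only the classes the filtering
cascade distinguishes are modelled; indels and multi-isoform arbitration are
out of scope (one transcript per gene).

Conventions:

* Exon/CDS intervals are 0-based half-open; VCF positions are 1-based.
* CDS features in our GTF dialect INCLUDE the stop codon, so
  ``protein_length = CDS_length/3 - 1``.
* Splice donor/acceptor sites are the 2 intronic bases flanking each exon
  boundary (the canonical GT/AG positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from ameloseq.formats import TargetInterval, VariantRecord

HIGH_CONSEQUENCE = frozenset({"missense", "stop_gain", "splice_donor", "splice_acceptor"})

CONSEQUENCE_CLASSES = (
    "missense",
    "stop_gain",
    "splice_donor",
    "splice_acceptor",
    "synonymous",
    "stop_loss",
    "start_loss",
    "intronic",
    "noncoding",
    "intergenic",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceMismatchError(ValueError):
    """The VCF REF allele disagrees with the reference genome at the locus."""


@dataclass
class TranscriptModel:
    """One protein-coding transcript (exons, CDS bounds, strand)."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[TargetInterval]  # sorted by genomic start, non-overlapping
    cds_start: int  # genomic, 0-based inclusive; stop codon included
    cds_end: int  # genomic, 0-based exclusive

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if sum(e - s for s, e in self.cds_intervals()) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Genomic (start, end) pieces of the translated region, genome order."""
        out = []
        for ex in self.exons:
            s, e = max(ex.start, self.cds_start), min(ex.end, self.cds_end)
            if s < e:
                out.append((s, e))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1

    def cds_genomic_positions(self) -> list[int]:
        """0-based genomic positions of CDS bases in TRANSCRIPT order."""
        pos = [p for s, e in self.cds_intervals() for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, genome) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.cds_intervals())
        if self.strand == "-":
            seq = seq[::-1].translate(_COMPLEMENT)
        return seq.upper()

    def cds_index_of(self, pos_1based: int) -> Optional[int]:
        """Transcript-order CDS offset of a genomic position, or None."""
        p = pos_1based - 1
        off = 0
        for s, e in self.cds_intervals():
            if s <= p < e:
                fwd = off + (p - s)
                if self.strand == "-":
                    return self.cds_length - 1 - fwd
                return fwd
            off += e - s
        return None

    def codon_genomic_positions(self, protein_pos: int) -> tuple[int, int, int]:
        """1-based genomic positions of the three bases of a codon."""
        if not 1 <= protein_pos <= self.protein_length:
            raise ValueError(f"protein position {protein_pos} outside 1..{self.protein_length}")
        positions = self.cds_genomic_positions()
        i = (protein_pos - 1) * 3
        return tuple(positions[i + k] + 1 for k in range(3))

    def splice_windows(self) -> dict[int, str]:
        """Map 1-based intronic genomic positions to 'donor'/'acceptor'."""
        win: dict[int, str] = {}
        for a, b in zip(self.exons, self.exons[1:]):
            left = (a.end + 1, a.end + 2)  # first two intron bases, genome order
            right = (b.start - 1, b.start)  # last two intron bases, 1-based
            if self.strand == "+":
                donor, acceptor = left, right
            else:
                donor, acceptor = right, left
            for p in donor:
                win[p] = "donor"
            for p in acceptor:
                win[p] = "acceptor"
        return win


@dataclass
class ConsequenceCall:
    """Classification of one SNV against one transcript."""

    variant: VariantRecord
    transcript_id: str
    gene_symbol: str
    klass: str
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.klass not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.klass!r}")

    @property
    def protein_change(self) -> Optional[str]:
        if self.protein_pos is None:
            return None
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"


def is_high_consequence(call: ConsequenceCall) -> bool:
    """True iff the class is one the cascade retains
    (missense, stop-gain, splice donor/acceptor)."""
    return call.klass in HIGH_CONSEQUENCE


def classify(variant: VariantRecord, tx: TranscriptModel, genome) -> ConsequenceCall:
    """Classify one SNV against one transcript.

    ``genome`` is any mapping of contig name to sequence string. The REF
    allele must match the genome at the locus (plus-strand orientation);
    a mismatch raises :class:`ReferenceMismatchError`.
    """
    if variant.chrom != tx.chrom:
        return _call(variant, tx, "intergenic")
    ref_base = genome[variant.chrom][variant.pos - 1].upper()
    if ref_base != variant.ref_allele:
        raise ReferenceMismatchError(
            f"REF {variant.ref_allele} != genome {ref_base} at {variant.chrom}:{variant.pos}"
        )
    p = variant.pos  # 1-based
    if p <= tx.start or p > tx.end:
        return _call(variant, tx, "intergenic")

    cds_idx = tx.cds_index_of(p)
    if cds_idx is None:
        in_exon = any(ex.contains_pos(p) for ex in tx.exons)
        if in_exon:
            return _call(variant, tx, "noncoding")
        window = tx.splice_windows().get(p)
        if window == "donor":
            return _call(variant, tx, "splice_donor")
        if window == "acceptor":
            return _call(variant, tx, "splice_acceptor")
        return _call(variant, tx, "intronic")

    cds_seq = tx.cds_sequence(genome)
    codon_idx, within = divmod(cds_idx, 3)
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    ref_allele, alt_allele = variant.ref_allele, variant.alt_allele
    if tx.strand == "-":
        ref_allele = ref_allele.translate(_COMPLEMENT)
        alt_allele = alt_allele.translate(_COMPLEMENT)
    assert codon[within] == ref_allele, "CDS/genome bookkeeping error"
    mutant = codon[:within] + alt_allele + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutant).translate())

    is_stop_codon = codon_idx == tx.protein_length
    if alt_aa == ref_aa:
        klass = "synonymous"
        return _call(variant, tx, klass)
    if is_stop_codon:
        # the terminal codon: ref_aa is '*'; losing it is stop_loss
        return _call(variant, tx, "stop_loss")
    if codon_idx == 0:
        # any non-synonymous change in the initiation codon, including one
        # that introduces a stop, abolishes the start: start_loss wins
        return _call(variant, tx, "start_loss")
    if alt_aa == "*":
        return _call(
            variant, tx, "stop_gain", protein_pos=codon_idx + 1, ref_aa=ref_aa, alt_aa=alt_aa
        )
    return _call(variant, tx, "missense", protein_pos=codon_idx + 1, ref_aa=ref_aa, alt_aa=alt_aa)


def _call(variant, tx, klass, protein_pos=None, ref_aa=None, alt_aa=None) -> ConsequenceCall:
    call = ConsequenceCall(
        variant=variant,
        transcript_id=tx.transcript_id,
        gene_symbol=tx.gene_symbol,
        klass=klass,
        protein_pos=protein_pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )
    variant.annotations["gene"] = tx.gene_symbol
    variant.annotations["consequence"] = klass
    if call.protein_change:
        variant.annotations["protein_change"] = call.protein_change
    return call


def classify_against_transcripts(
    variant: VariantRecord, transcripts: list[TranscriptModel], genome
) -> ConsequenceCall:
    """Classify against the (single) transcript overlapping the variant.

    With no overlapping transcript the call is intergenic against a sentinel
    transcript id. Transcript models are assumed non-overlapping (toy genome
    and v1 scope: one transcript per gene).
    """
    for tx in transcripts:
        if tx.chrom == variant.chrom and tx.start < variant.pos <= tx.end:
            return classify(variant, tx, genome)
    call = ConsequenceCall(
        variant=variant, transcript_id="", gene_symbol="", klass="intergenic"
    )
    variant.annotations.setdefault("gene", "")
    variant.annotations["consequence"] = "intergenic"
    return call


def snv_for_protein_change(
    tx: TranscriptModel, genome, protein_pos: int, ref_aa: str, alt_aa: str
) -> tuple[str, int, str, str]:
    """Design the genomic SNV (chrom, pos, ref, alt) producing a protein change.

    Scans the codon's three positions and three alternative bases in fixed
    order and returns the first substitution whose translation is ``alt_aa``.
    Raises if the change is not reachable by a single-nucleotide substitution.
    """
    cds_seq = tx.cds_sequence(genome)
    codon = cds_seq[(protein_pos - 1) * 3 : (protein_pos - 1) * 3 + 3]
    if str(Seq(codon).translate()) != ref_aa:
        raise ValueError(
            f"{tx.gene_symbol} codon {protein_pos} is {codon} ({Seq(codon).translate()}), not {ref_aa}"
        )
    genomic = tx.codon_genomic_positions(protein_pos)
    for within in range(3):
        for base in "ACGT":
            if base == codon[within]:
                continue
            mutant = codon[:within] + base + codon[within + 1 :]
            if str(Seq(mutant).translate()) == alt_aa:
                ref_b, alt_b = codon[within], base
                if tx.strand == "-":
                    ref_b = ref_b.translate(_COMPLEMENT)
                    alt_b = alt_b.translate(_COMPLEMENT)
                return (tx.chrom, genomic[within], ref_b, alt_b)
    raise ValueError(f"{ref_aa}{protein_pos}{alt_aa} not reachable by one SNV from {codon}")


# ---------------------------------------------------------------------------
# GTF / FASTA input
# ---------------------------------------------------------------------------

def _gtf_attributes(text: str) -> dict:
    out = {}
    for chunk in text.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Only ``exon`` and ``CDS`` features are used; one transcript per gene is
    assumed. CDS features must include the stop codon (the dialect this
    package writes).
    """
    exons: dict[str, list[TargetInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GTF line: {ln[:80]!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = _gtf_attributes(attrs)
            tid = a["transcript_id"]
            gene = a.get("gene_name", a.get("gene_id", tid))
            meta[tid] = (gene, chrom, strand)
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature == "exon":
                exons.setdefault(tid, []).append(TargetInterval(chrom, s, e, label=tid))
            else:
                cds.setdefault(tid, []).append((s, e))
    models = []
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in cds:
            continue
        cds_start = min(s for s, _ in cds[tid])
        cds_end = max(e for _, e in cds[tid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in models:
            attrs = (
                f'gene_id "{tx.gene_symbol}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_symbol}";'
            )
            rows = [(tx.start, tx.end, "transcript")]
            for ex in tx.exons:
                rows.append((ex.start, ex.end, "exon"))
            for s, e in tx.cds_intervals():
                rows.append((s, e, "CDS"))
            for s, e, feature in rows:
                fh.write(
                    f"{tx.chrom}\tameloseq\t{feature}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def load_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file into a contig -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
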