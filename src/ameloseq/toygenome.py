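"""Deterministic builder of the packaged toy canine genome.

The simulator and the test suite run against a small synthetic "canine"
genome: ~10 protein-coding genes on two contigs, multi-exon, both strands,
with canonical GT/AG introns. Hotspot-bearing genes carry the codons that
make the canonical driver substitutions reachable by a single nucleotide
change (HRAS codon 61 CAA so that A>G gives CGA, Q61R; BRAF codon 595 GTG so
that the orthologous V>E change is one substitution), and the toy human BRAF
ortholog carries a 5-residue insertion upstream of the kinase hotspot so
that human position 600 corresponds to canine 595, as in the real proteins.

Everything is generated from a fixed seed; the packaged FASTA/GTF/BED
fixtures under ``data/`` are this builder's verbatim output (a test guards
the correspondence), and ``scripts/regenerate_fixtures.py`` rewrites them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from Bio.Seq import Seq

from ameloseq.consequence import TranscriptModel, write_gtf
from ameloseq.formats import TargetInterval, write_bed

BUILDER_SEED = 791204  # fixed: the packaged fixtures are this seed's output

_CODON_TABLE: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            _CODON_TABLE.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s[::-1].translate(_COMPLEMENT)


@dataclass
class GeneSpec:
    name: str
    chrom: str
    strand: str
    length: int  # residues, excluding stop
    n_exons: int
    forced_codons: dict = field(default_factory=dict)  # protein_pos -> codon


#: the toy gene complement; hotspot codons are forced so canonical driver
#: substitutions exist as single-base changes
GENES = [
    GeneSpec("HRAS", "chr1", "+", 100, 2, {12: "GGT", 13: "GGC", 61: "CAA"}),
    GeneSpec("KRAS", "chr1", "+", 95, 3, {12: "GGT", 13: "GGC", 61: "CAA"}),
    GeneSpec("NRAS", "chr1", "-", 90, 2, {61: "CAA"}),
    GeneSpec("TP53", "chr1", "-", 110, 3, {}),
    GeneSpec("PTEN", "chr1", "+", 85, 1, {}),
    GeneSpec("GATA3", "chr1", "+", 70, 2, {}),
    GeneSpec("BRAF", "chr2", "-", 640, 4, {595: "GTG"}),
    GeneSpec("SMO", "chr2", "+", 560, 3, {473: "GAT", 535: "TGG"}),
    GeneSpec("EGFR", "chr2", "+", 120, 2, {}),
    GeneSpec("MYC", "chr2", "-", 105, 2, {}),
]

#: human ortholog edits: BRAF gets a 5-residue human-specific insertion after
#: canine position 570 (so canine 595 is human 600); TP53 gets three point
#: substitutions to exercise non-identity alignment
HUMAN_BRAF_INSERT_AFTER = 570
HUMAN_BRAF_INSERT = "GGSGG"
HUMAN_TP53_SUBS = {10: "K", 45: "S", 90: "A"}


@dataclass
class ToyGenome:
    genome: dict  # chrom -> sequence
    transcripts: list  # of TranscriptModel
    canine_proteins: dict  # gene -> protein sequence
    human_proteins: dict
    targets: list  # of TargetInterval

    def transcript(self, gene: str) -> TranscriptModel:
        return next(tx for tx in self.transcripts if tx.gene_symbol == gene)


def _random_protein(rng: np.random.Generator, spec: GeneSpec) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY".replace("M", "")  # M only at start
    body = "".join(rng.choice(list(aas)) for _ in range(spec.length - 1))
    prot = "M" + body
    for pos, codon in spec.forced_codons.items():
        aa = str(Seq(codon).translate())
        prot = prot[: pos - 1] + aa + prot[pos:]
    return prot


def _back_translate(rng: np.random.Generator, protein: str, forced: dict) -> str:
    codons = []
    for i, aa in enumerate(protein, start=1):
        if i in forced:
            codons.append(forced[i])
        else:
            codons.append(str(rng.choice(_CODON_TABLE[aa])))
    codons.append(str(rng.choice(["TAA", "TGA", "TAG"])))
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


def _split_lengths(rng: np.random.Generator, total: int, parts: int, min_len: int = 12) -> list[int]:
    if parts == 1:
        return [total]
    while True:
        cuts = sorted(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
        lens = np.diff([0, *cuts, total])
        if (lens >= min_len).all():
            return [int(v) for v in lens]


def build_toy_genome(seed: int = BUILDER_SEED) -> ToyGenome:
    """Build the full toy genome deterministically from a seed."""
    rng = np.random.default_rng(seed)
    contigs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    offsets = {"chr1": 0, "chr2": 0}
    transcripts: list[TranscriptModel] = []
    canine_proteins: dict[str, str] = {}
    targets: list[TargetInterval] = []

    for spec in GENES:
        protein = _random_protein(rng, spec)
        canine_proteins[spec.name] = protein
        cds = _back_translate(rng, protein, spec.forced_codons)

        exon_lens = _split_lengths(rng, len(cds), spec.n_exons)
        sense_parts: list[tuple[str, bool]] = []  # (seq, is_exon)
        p = 0
        for k, el in enumerate(exon_lens):
            sense_parts.append((cds[p : p + el], True))
            p += el
            if k < len(exon_lens) - 1:
                intron = "GT" + _random_dna(rng, int(rng.integers(60, 150))) + "AG"
                sense_parts.append((intron, False))
        sense_seq = "".join(s for s, _ in sense_parts)

        spacer = _random_dna(rng, int(rng.integers(150, 300)))
        contigs[spec.chrom].append(spacer)
        offsets[spec.chrom] += len(spacer)
        g0 = offsets[spec.chrom]

        if spec.strand == "+":
            genomic_seq = sense_seq
            exon_ivs = []
            off = 0
            for s, is_exon in sense_parts:
                if is_exon:
                    exon_ivs.append(TargetInterval(spec.chrom, g0 + off, g0 + off + len(s), spec.name))
                off += len(s)
        else:
            genomic_seq = _revcomp(sense_seq)
            L = len(sense_seq)
            exon_ivs = []
            off = 0
            for s, is_exon in sense_parts:
                if is_exon:
                    exon_ivs.append(
                        TargetInterval(spec.chrom, g0 + L - off - len(s), g0 + L - off, spec.name)
                    )
                off += len(s)
            exon_ivs.reverse()

        contigs[spec.chrom].append(genomic_seq)
        offsets[spec.chrom] += len(genomic_seq)

        tx = TranscriptModel(
            transcript_id=f"{spec.name}-201",
            gene_symbol=spec.name,
            chrom=spec.chrom,
            strand=spec.strand,
            exons=exon_ivs,
            cds_start=exon_ivs[0].start,
            cds_end=exon_ivs[-1].end,
        )
        transcripts.append(tx)
        for iv in exon_ivs:
            targets.append(TargetInterval(iv.chrom, max(0, iv.start - 10), iv.end + 10, spec.name))

    for chrom in contigs:
        contigs[chrom].append(_random_dna(rng, int(rng.integers(150, 300))))
    genome = {c: "".join(parts) for c, parts in contigs.items()}

    # verify translation round-trips before anything downstream trusts it
    for tx in transcripts:
        cds_seq = tx.cds_sequence(genome)
        prot = str(Seq(cds_seq).translate())
        assert prot[-1] == "*" and prot[:-1] == canine_proteins[tx.gene_symbol], tx.gene_symbol

    human_proteins = dict(canine_proteins)
    braf = canine_proteins["BRAF"]
    human_proteins["BRAF"] = (
        braf[:HUMAN_BRAF_INSERT_AFTER] + HUMAN_BRAF_INSERT + braf[HUMAN_BRAF_INSERT_AFTER:]
    )
    tp53 = list(canine_proteins["TP53"])
    for pos, aa in HUMAN_TP53_SUBS.items():
        tp53[pos - 1] = aa
    human_proteins["TP53"] = "".join(tp53)

    targets = sorted(targets, key=lambda t: (t.chrom, t.start))
    return ToyGenome(genome, transcripts, canine_proteins, human_proteins, targets)


def write_fixtures(toy: ToyGenome, data_dir) -> None:
    """Write the toy genome as FASTA/GTF/BED/protein-FASTA fixture files."""
    from pathlib import Path

    data_dir = Path(data_dir)
    with open(data_dir / "toy_genome.fa", "w") as fh:
        for chrom, seq in toy.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_gtf(toy.transcripts, data_dir / "toy_genes.gtf")
    write_bed(toy.targets, data_dir / "targets.bed")
    for name, proteins in (("proteins_canine.fa", toy.canine_proteins), ("proteins_human.fa", toy.human_proteins)):
        with open(data_dir / name, "w") as fh:
            for gene, seq in proteins.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
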