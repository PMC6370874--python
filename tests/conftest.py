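"""Shared fixtures: toy reference resources and helpers for building
small transcripts and VCF files on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from ameloseq import refdata
from ameloseq.consequence import TranscriptModel
from ameloseq.formats import TargetInterval
from ameloseq.toygenome import _back_translate, _random_dna


@pytest.fixture(scope="session")
def toy_genome():
    return refdata.toy_genome()


@pytest.fixture(scope="session")
def toy_transcripts():
    return {tx.gene_symbol: tx for tx in refdata.toy_transcripts()}


@pytest.fixture(scope="session")
def ortholog_maps():
    return refdata.ortholog_maps()


def make_random_transcript(rng: np.random.Generator, strand=None, chrom="t1", gene="GENE"):
    """A small random transcript embedded in a random genome contig.

    Returns (genome_dict, TranscriptModel, protein). 1-3 exons, either
    strand, canonical GT/AG introns, no UTRs.
    """
    from Bio.Seq import Seq

    strand = strand or str(rng.choice(["+", "-"]))
    n_res = int(rng.integers(8, 25))
    aas = "ACDEFGHIKLNPQRSTVWY"
    protein = "M" + "".join(str(rng.choice(list(aas))) for _ in range(n_res - 1))
    cds = _back_translate(rng, protein, {})
    n_exons = int(rng.integers(1, 4))
    # split CDS into exon pieces of >= 4 bp
    while True:
        if n_exons == 1:
            lens = [len(cds)]
            break
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
        lens = np.diff([0, *cuts, len(cds)]).tolist()
        if min(lens) >= 4:
            break
    parts, p = [], 0
    for k, el in enumerate(lens):
        parts.append((cds[p : p + el], True))
        p += el
        if k < len(lens) - 1:
            parts.append(("GT" + _random_dna(rng, int(rng.integers(8, 30))) + "AG", False))
    sense = "".join(s for s, _ in parts)
    if strand == "-":
        genomic = str(Seq(sense).reverse_complement())
    else:
        genomic = sense
    left = _random_dna(rng, int(rng.integers(20, 60)))
    right = _random_dna(rng, int(rng.integers(20, 60)))
    g0 = len(left)
    exon_ivs, off = [], 0
    for s, is_exon in parts:
        if is_exon:
            if strand == "+":
                exon_ivs.append(TargetInterval(chrom, g0 + off, g0 + off + len(s), gene))
            else:
                L = len(sense)
                exon_ivs.append(TargetInterval(chrom, g0 + L - off - len(s), g0 + L - off, gene))
        off += len(s)
    exon_ivs.sort(key=lambda iv: iv.start)
    tx = TranscriptModel(
        transcript_id=f"{gene}-1",
        gene_symbol=gene,
        chrom=chrom,
        strand=strand,
        exons=exon_ivs,
        cds_start=exon_ivs[0].start,
        cds_end=exon_ivs[-1].end,
    )
    genome = {chrom: left + genomic + right}
    return genome, tx, protein


def write_text_vcf(path, body_lines, contigs=("chr1", "chr2"), sample="S1"):
    """Write a minimal hand-rolled VCF file for parser tests."""
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in contigs]
    header += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##INFO=<ID=DP4,Number=4,Type=Integer,Description="strand depths">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">',
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="ref obs">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="alt obs">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for ln in body_lines:
            fh.write(ln + "\n")
    return path
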