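"""Consequence classification vs a translate-the-whole-mutant-CDS oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from ameloseq.consequence import (
    ReferenceMismatchError,
    classify,
    is_high_consequence,
    snv_for_protein_change,
)
from ameloseq.formats import VariantRecord
from conftest import make_random_transcript


def oracle_classify(variant, tx, genome):
    """Independent brute-force classification.

    Splice windows from first principles on the exon list; coding calls by
    rebuilding the whole mutant genome, re-extracting and translating the
    full CDS, and diffing the two proteins.
    """
    pos0 = variant.pos - 1
    if not (tx.start < variant.pos <= tx.end):
        return "intergenic", None
    in_exon = any(ex.start <= pos0 < ex.end for ex in tx.exons)
    if not in_exon:
        donors, acceptors = set(), set()
        for a, b in zip(tx.exons, tx.exons[1:]):
            left = {a.end, a.end + 1}  # 0-based first two intron bases
            right = {b.start - 2, b.start - 1}
            if tx.strand == "+":
                donors |= left
                acceptors |= right
            else:
                donors |= right
                acceptors |= left
        if pos0 in donors:
            return "splice_donor", None
        if pos0 in acceptors:
            return "splice_acceptor", None
        return "intronic", None
    if not (tx.cds_start <= pos0 < tx.cds_end):
        return "noncoding", None

    mutant_contig = (
        genome[tx.chrom][:pos0] + variant.alt_allele + genome[tx.chrom][pos0 + 1 :]
    )
    ref_prot = str(Seq(tx.cds_sequence(genome)).translate())
    mut_prot = str(Seq(tx.cds_sequence({tx.chrom: mutant_contig})).translate())
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    if not diffs:
        return "synonymous", None
    (i,) = diffs
    if i == 0:
        return "start_loss", None
    if ref_prot[i] == "*":
        return "stop_loss", None
    if mut_prot[i] == "*":
        return "stop_gain", i + 1
    return "missense", i + 1


def all_snvs_of(tx, genome, region=None):
    chrom_seq = genome[tx.chrom]
    lo, hi = region if region else (tx.start, tx.end)
    for pos0 in range(lo, hi):
        ref = chrom_seq[pos0]
        if ref not in "ACGT":
            continue
        for alt in "ACGT":
            if alt != ref:
                yield VariantRecord(tx.chrom, pos0 + 1, ref, alt, 100, 30)


class TestWorkedExamples:
    def test_q61r_on_toy_hras(self, toy_genome, toy_transcripts):
        tx = toy_transcripts["HRAS"]
        chrom, pos, ref, alt = snv_for_protein_change(tx, toy_genome, 61, "Q", "R")
        assert (ref, alt) == ("A", "G")  # CAA -> CGA at codon position 2
        call = classify(VariantRecord(chrom, pos, ref, alt, 72, 20), tx, toy_genome)
        assert call.klass == "missense"
        assert (call.protein_pos, call.ref_aa, call.alt_aa) == (61, "Q", "R")
        assert call.protein_change == "Q61R"

    def test_v595e_on_minus_strand_braf(self, toy_genome, toy_transcripts):
        tx = toy_transcripts["BRAF"]
        chrom, pos, ref, alt = snv_for_protein_change(tx, toy_genome, 595, "V", "E")
        call = classify(VariantRecord(chrom, pos, ref, alt, 197, 57), tx, toy_genome)
        assert call.protein_change == "V595E"

    def test_first_intronic_base_is_splice_donor(self, toy_genome, toy_transcripts):
        tx = toy_transcripts["HRAS"]  # plus strand, 2 exons
        donor_pos0 = tx.exons[0].end  # first intron base, canonical G of GT
        assert toy_genome[tx.chrom][donor_pos0] == "G"
        ref = toy_genome[tx.chrom][donor_pos0]
        alt = "A" if ref != "A" else "C"
        call = classify(VariantRecord(tx.chrom, donor_pos0 + 1, ref, alt, 50, 20), tx, toy_genome)
        assert call.klass == "splice_donor"

    def test_reference_mismatch_is_error(self, toy_genome, toy_transcripts):
        tx = toy_transcripts["HRAS"]
        base = toy_genome[tx.chrom][tx.start + 1]
        wrong = "A" if base != "A" else "C"
        other = "G" if wrong != "G" else "T"
        with pytest.raises(ReferenceMismatchError):
            classify(VariantRecord(tx.chrom, tx.start + 2, wrong, other, 50, 10), tx, toy_genome)


def test_exhaustive_enumeration_matches_oracle_on_toy_gene(toy_genome, toy_transcripts):
    """Every possible SNV over a packaged small CDS classifies identically
    to the brute-force mutant-translation oracle (includes flanks/introns)."""
    tx = toy_transcripts["GATA3"]  # small 2-exon plus-strand gene
    n = 0
    for v in all_snvs_of(tx, toy_genome, region=(tx.start - 5, tx.end + 5)):
        expected, ppos = oracle_classify(v, tx, toy_genome)
        call = classify(v, tx, toy_genome)
        assert call.klass == expected, f"{v.chrom}:{v.pos} {v.ref_allele}>{v.alt_allele}"
        if ppos is not None:
            assert call.protein_pos == ppos
        n += 1
    assert n > 400


@pytest.mark.parametrize("seed", range(12))
def test_random_transcripts_match_oracle_both_strands(seed):
    """Property: on random small transcripts (either strand, 1-3 exons) the
    classifier agrees with the oracle for every possible SNV."""
    rng = np.random.default_rng(1000 + seed)
    genome, tx, _ = make_random_transcript(rng)
    for v in all_snvs_of(tx, genome):
        expected, ppos = oracle_classify(v, tx, genome)
        call = classify(v, tx, genome)
        assert call.klass == expected, f"{tx.strand} {v.pos} {v.ref_allele}>{v.alt_allele}"
        if ppos is not None:
            assert call.protein_pos == ppos


def test_strand_symmetry_mirrored_gene(toy_genome, toy_transcripts):
    """A coding SNV and its reverse-complement mirror on the opposite strand
    give the same protein-level call."""
    rng = np.random.default_rng(7)
    genome, tx, protein = make_random_transcript(rng, strand="+", gene="FWD")
    contig = genome[tx.chrom]
    rc = str(Seq(contig).reverse_complement())
    L = len(contig)
    from ameloseq.consequence import TranscriptModel
    from ameloseq.formats import TargetInterval

    mirrored_exons = [
        TargetInterval(tx.chrom, L - e.end, L - e.start, "REV") for e in tx.exons
    ]
    tx_rc = TranscriptModel(
        transcript_id="REV-1",
        gene_symbol="REV",
        chrom=tx.chrom,
        strand="-",
        exons=mirrored_exons,
        cds_start=L - tx.cds_end,
        cds_end=L - tx.cds_start,
    )
    genome_rc = {tx.chrom: rc}
    comp = str.maketrans("ACGT", "TGCA")
    for v in all_snvs_of(tx, genome):
        call = classify(v, tx, genome)
        mirrored = VariantRecord(
            tx.chrom,
            L - v.pos + 1,
            v.ref_allele.translate(comp),
            v.alt_allele.translate(comp),
            100,
            30,
        )
        call_rc = classify(mirrored, tx_rc, genome_rc)
        assert (call.klass, call.protein_pos, call.ref_aa, call.alt_aa) == (
            call_rc.klass,
            call_rc.protein_pos,
            call_rc.ref_aa,
            call_rc.alt_aa,
        )


def test_protein_pos_shifts_one_residue_per_codon(toy_genome, toy_transcripts):
    """protein_pos advances by exactly 1 for every 3-bp shift within one exon."""
    tx = toy_transcripts["PTEN"]  # single-exon plus-strand gene
    positions = []
    for k in range(1, 11):
        pos0 = tx.cds_start + 3 * k + 1  # second base of codon k+1
        ref = toy_genome[tx.chrom][pos0]
        for alt in "ACGT":
            if alt == ref:
                continue
            call = classify(VariantRecord(tx.chrom, pos0 + 1, ref, alt, 50, 20), tx, toy_genome)
            if call.klass == "missense":
                positions.append(call.protein_pos)
                break
    assert positions == [p + 1 for p in range(1, len(positions) + 1)]


@pytest.mark.parametrize(
    "klass,expected",
    [
        ("missense", True),
        ("stop_gain", True),
        ("splice_donor", True),
        ("splice_acceptor", True),
        ("synonymous", False),
        ("stop_loss", False),
        ("start_loss", False),
        ("intronic", False),
        ("intergenic", False),
    ],
)
def test_high_consequence_is_the_closed_retained_set(klass, expected):
    from ameloseq.consequence import ConsequenceCall

    v = VariantRecord("chr1", 10, "A", "G", 50, 20)
    call = ConsequenceCall(
        variant=v, transcript_id="t", gene_symbol="g", klass=klass,
        protein_pos=5 if klass in ("missense", "stop_gain") else None,
        ref_aa="Q" if klass in ("missense", "stop_gain") else None,
        alt_aa="R" if klass == "missense" else ("*" if klass == "stop_gain" else None),
    )
    assert is_high_consequence(call) is expected
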