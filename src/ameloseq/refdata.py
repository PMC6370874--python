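"""Packaged reference resources and pipeline wiring.

Loads the toy genome, transcript models, ortholog protein pairs, demo
hotspot catalog and demo cancer-gene list shipped under ``data/``, and
assembles the callbacks the filtering cascade needs. All loaders are cached:
the ortholog alignments are recomputed once per process.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ilr
from pathlib import Path

from ameloseq import consequence as cq
from ameloseq import hotspot_map as hm
from ameloseq.formats import read_bed, read_gene_list


def data_path(name: str) -> Path:
    return Path(_ilr.files("ameloseq").joinpath("data", name))


@lru_cache(maxsize=1)
def toy_genome() -> dict:
    return cq.load_fasta(data_path("toy_genome.fa"))


@lru_cache(maxsize=1)
def toy_transcripts() -> tuple:
    return tuple(cq.read_gtf(data_path("toy_genes.gtf")))


@lru_cache(maxsize=1)
def toy_targets() -> tuple:
    return tuple(read_bed(data_path("targets.bed")))


@lru_cache(maxsize=1)
def demo_gene_list() -> frozenset:
    return frozenset(read_gene_list(data_path("cancer_genes.txt")))


@lru_cache(maxsize=1)
def demo_hotspot_catalog() -> tuple:
    return tuple(hm.read_hotspot_catalog(data_path("hotspots.tsv")))


@lru_cache(maxsize=1)
def ortholog_maps() -> dict:
    """Human->canine ortholog maps for every gene with both protein fixtures."""
    human = cq.load_fasta(data_path("proteins_human.fa"))
    canine = cq.load_fasta(data_path("proteins_canine.fa"))
    maps = {}
    for gene in sorted(set(human) & set(canine)):
        maps[gene] = hm.align_orthologs(human[gene], canine[gene], gene_symbol=gene)
    return maps


@lru_cache(maxsize=1)
def hotspot_loci() -> frozenset:
    """Genomic loci of all mapped canine hotspot codons on the toy genome."""
    return frozenset(
        hm.hotspot_genomic_loci(demo_hotspot_catalog(), ortholog_maps(), toy_transcripts())
    )


def table1_variant_records() -> list:
    """VariantRecords for the cohort-table cases with measured depth/VAF.

    Each case's driver mutation is placed at the corresponding toy-genome
    hotspot locus with the printed read depth and the alt count that
    reproduces the printed VAF, so the evidence filter and rescue can be
    exercised on the in-study numbers.
    """
    from ameloseq.formats import VariantRecord, load_table1_fixture

    genome = toy_genome()
    by_gene = {tx.gene_symbol: tx for tx in toy_transcripts()}
    records = []
    for case in load_table1_fixture():
        if case.vaf is None or case.read_depth is None or case.mutation_call is None:
            continue
        gene, pchange = case.mutation_call
        ref_aa, ppos, alt_aa = pchange[0], int(pchange[1:-1]), pchange[-1]
        chrom, pos, ref, alt = cq.snv_for_protein_change(
            by_gene[gene], genome, ppos, ref_aa, alt_aa
        )
        alt_depth = round(case.vaf * case.read_depth)
        records.append(
            VariantRecord(
                chrom, pos, ref, alt, case.read_depth, alt_depth, sample_id=case.case_id
            )
        )
    return records


def consequence_fn(variant) -> cq.ConsequenceCall:
    return cq.classify_against_transcripts(variant, list(toy_transcripts()), toy_genome())


def hotspot_fn(call):
    return hm.match_variant_to_hotspot(call, demo_hotspot_catalog(), ortholog_maps())
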