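"""External file formats and core record types.

Everything the pipeline reads or writes passes through here: VCF 4.x variant
calls (via pysam), BED capture targets, TSV gene lists / hotspot catalogs /
reports, and the packaged 24-case cohort table.

Coordinate conventions: VCF and protein positions are 1-based; all interval
arithmetic (targets, exons) is 0-based half-open, as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: annotation key set accrued by later pipeline stages
ANNOTATION_KEYS = ("gene", "consequence", "protein_change", "hotspot_match", "filter_status")


class VcfParseError(ValueError):
    """A VCF record could not be interpreted; message names the data line."""


@dataclass
class VariantRecord:
    """One called single-nucleotide variant.

    ``total_depth`` is ``None`` when the caller emitted no usable depth
    fields; such records carry ``annotations['no_evidence'] = True`` and are
    never silently dropped.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    total_depth: Optional[int]
    alt_depth: Optional[int]
    sample_id: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}>{self.alt_allele!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.total_depth is not None:
            if self.total_depth < 0:
                raise ValueError("total_depth < 0")
            if self.alt_depth is None or not 0 <= self.alt_depth <= self.total_depth:
                raise ValueError(
                    f"alt_depth {self.alt_depth} outside [0, {self.total_depth}] "
                    f"at {self.chrom}:{self.pos}"
                )

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction, or None without depth evidence."""
        if self.total_depth is None or self.total_depth == 0:
            return None
        return self.alt_depth / self.total_depth

    @property
    def site(self) -> tuple:
        return (self.chrom, self.pos)

    @property
    def site_allele(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class TargetInterval:
    """Half-open 0-based genomic interval (capture target, exon, segment span)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass
class CohortCase:
    """One tumor case: metadata plus its nominated driver call, if any."""

    case_id: str
    location: str
    tissue: str
    breed: str = ""
    mutation_call: Optional[tuple] = None  # (gene, protein_change)
    vaf: Optional[float] = None
    read_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.location not in ("mandible", "maxilla"):
            raise ValueError(f"unknown anatomic site {self.location!r}")
        if self.tissue not in ("FFPE", "fresh"):
            raise ValueError(f"unknown tissue type {self.tissue!r}")
        if self.vaf is not None and not 0.0 < self.vaf < 1.0:
            raise ValueError(f"vaf {self.vaf} outside (0,1)")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _sample_field(rec: pysam.VariantRecord, key: str):
    if rec.samples and key in rec.samples[0]:
        val = rec.samples[0][key]
        if val is not None and val != (None,):
            return val
    return None


def _depths_for_alt(rec: pysam.VariantRecord, alt_index: int):
    """Extract (total_depth, alt_depth) for one ALT allele.

    Fallback order across caller dialects: FORMAT AD, then FORMAT RO/AO
    (freebayes-style), then INFO DP4 (mpileup-style, first ALT only).
    Total depth prefers FORMAT DP, then INFO DP, then the sum of the
    allele-depth field that was used.
    """
    total = _sample_field(rec, "DP")
    if total is None and "DP" in rec.info:
        total = rec.info["DP"]

    alt_reads = None
    ad = _sample_field(rec, "AD")
    if ad is not None and len(ad) > alt_index + 1:
        alt_reads = ad[alt_index + 1]
        if total is None:
            total = sum(x for x in ad if x is not None)
    if alt_reads is None:
        ao = _sample_field(rec, "AO")
        ro = _sample_field(rec, "RO")
        if ao is not None:
            ao = ao if isinstance(ao, tuple) else (ao,)
            if len(ao) > alt_index:
                alt_reads = ao[alt_index]
                if total is None and ro is not None:
                    total = int(ro) + sum(x for x in ao if x is not None)
    if alt_reads is None and "DP4" in rec.info and alt_index == 0:
        dp4 = rec.info["DP4"]
        alt_reads = int(dp4[2]) + int(dp4[3])
        if total is None:
            total = int(sum(dp4))

    if total is None or alt_reads is None:
        return None, None
    total = int(total)
    alt_reads = int(alt_reads)
    # clamp pathological caller output rather than erroring: DP can lag AD
    if alt_reads > total:
        total = alt_reads
    return total, alt_reads


def read_vcf(path, sample_id: Optional[str] = None) -> list[VariantRecord]:
    """Read SNV records from a VCF 4.x file.

    Multi-allelic records are split into one record per ALT; indel alleles are
    skipped with a logged count. Records without usable depth fields are kept
    and flagged ``no_evidence`` instead of being dropped.
    """
    path = str(path)
    out: list[VariantRecord] = []
    n_indel = 0
    with pysam.VariantFile(path) as vcf:
        if sample_id is None:
            samples = list(vcf.header.samples)
            sample_id = samples[0] if samples else Path(path).stem
        for line_no, rec in enumerate(vcf, start=1):
            try:
                if rec.alts is None:
                    continue
                for alt_index, alt in enumerate(rec.alts):
                    if len(rec.ref) != 1 or alt is None or len(alt) != 1 or alt == "*":
                        n_indel += 1
                        continue
                    total, alt_reads = _depths_for_alt(rec, alt_index)
                    v = VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        total_depth=total,
                        alt_depth=alt_reads,
                        sample_id=sample_id,
                    )
                    if total is None:
                        v.annotations["no_evidence"] = True
                    out.append(v)
            except ValueError as exc:
                raise VcfParseError(f"{path}: malformed record at data line {line_no}: {exc}") from exc
    if n_indel:
        logger.info("%s: skipped %d non-SNV allele(s)", path, n_indel)
    return out


def write_vcf(records: Sequence[VariantRecord], path, contigs: Optional[Iterable[str]] = None) -> None:
    """Write SNV records as a single-sample VCF 4.2 with DP and AD fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "ameloseq")
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Read depth")]
    )
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", "AD"),
            ("Number", "R"),
            ("Type", "Integer"),
            ("Description", "Allelic depths (ref,alt)"),
        ],
    )
    if contigs is None:
        seen = []
        for r in records:
            if r.chrom not in seen:
                seen.append(r.chrom)
        contigs = seen
    for c in contigs:
        header.contigs.add(c)
    sample = records[0].sample_id if records else "SAMPLE"
    header.add_sample(sample or "SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda v: (list(header.contigs).index(v.chrom), v.pos, v.alt_allele)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos, alleles=(r.ref_allele, r.alt_allele)
            )
            if r.total_depth is not None:
                rec.samples[0]["DP"] = r.total_depth
                rec.samples[0]["AD"] = (r.total_depth - r.alt_depth, r.alt_depth)
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def read_bed(path) -> list[TargetInterval]:
    """Read capture targets from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(TargetInterval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def write_bed(intervals: Sequence[TargetInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list; '#' comments allowed.

    Symbols are upper-cased and de-duplicated. An empty list is an error:
    a tumor-only cascade with no gene restriction is a misconfiguration.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for ln in fh:
            sym = ln.split("#", 1)[0].strip()
            if sym:
                genes.add(sym.upper())
    if not genes:
        raise ValueError(f"gene list {path} contains no symbols")
    return genes


def read_known_snp_sites(path) -> set[tuple]:
    """Load known germline SNP sites as a set of (chrom, pos, ref, alt)."""
    sites = set()
    for v in read_vcf(path, sample_id="sites"):
        sites.add(v.site_allele)
    return sites


# ---------------------------------------------------------------------------
# Packaged cohort table
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(_ilr.files("ameloseq").joinpath("data", name))


def load_table1_fixture() -> list[CohortCase]:
    """The packaged 24-case cohort table (case metadata, driver calls, VAFs)."""
    cases = []
    with open(_data_path("table1.tsv")) as fh:
        header = None
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            if header is None:
                header = ln.split("\t")
                continue
            row = dict(zip(header, ln.split("\t")))
            mut = row.get("mutation", "") or None
            call = None
            if mut:
                gene, pchange = mut.split("-", 1)
                call = (gene, pchange)
            vaf = row.get("vaf", "") or None
            depth = row.get("read_depth", "") or None
            cases.append(
                CohortCase(
                    case_id=row["case_id"],
                    location=row["location"].lower(),
                    tissue=row["tissue"],
                    breed=row.get("breed", ""),
                    mutation_call=call,
                    vaf=float(vaf) if vaf else None,
                    read_depth=int(depth) if depth else None,
                )
            )
    return cases
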