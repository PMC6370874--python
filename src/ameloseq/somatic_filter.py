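"""Tumor-only somatic filtering cascade with targeted low-VAF hotspot rescue.

Without a matched normal, somatic status is forced by a conjunction of
priors, applied in this order:

1. ``gene_list``   — the variant's gene is a canine ortholog of a known
                     human cancer gene;
2. ``known_snp``   — the site+allele is not a catalogued germline SNP;
3. ``evidence``    — read depth >= 20 and VAF within the 20-50% band that a
                     clonal heterozygous somatic mutation diluted by stroma
                     occupies (germline hets sit near 50%, homs near 100%);
4. ``consequence`` — missense, stop-gain or splice donor/acceptor;
5. ``hotspot``     — the protein change sits at the orthologous position of
                     a curated human cancer hotspot.

Stages are conjunctive, so the survivor SET is order-invariant; per-stage
rejection counts are not, and reports follow the order above.

The rescue pass emulates manual read inspection at hotspot loci: a variant
rejected only for sitting below the VAF band is recovered when it has at
least ``rescue_min_alt_reads`` supporting reads and VAF at or above
``rescue_vaf_floor``. Rescue never applies above the band (a high-VAF
failure looks germline, not low-purity somatic) and never demotes a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

from ameloseq.formats import VariantRecord

STAGES = ("gene_list", "known_snp", "evidence", "consequence", "hotspot")


@dataclass
class FilterConfig:
    """Thresholds and resources for the cascade."""

    min_depth: int = 20
    vaf_low: float = 0.20
    vaf_high: float = 0.50
    rescue_vaf_floor: float = 0.05
    rescue_min_alt_reads: int = 4
    gene_list: frozenset = frozenset()
    known_snp_sites: frozenset = frozenset()  # (chrom, pos, ref, alt)
    hotspot_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rescue_vaf_floor < self.vaf_low < self.vaf_high <= 1:
            raise ValueError(
                "need 0 < rescue_vaf_floor < vaf_low < vaf_high <= 1, got "
                f"{self.rescue_vaf_floor}, {self.vaf_low}, {self.vaf_high}"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class FilterTrace:
    """Per-variant record of every stage decision and the final status."""

    variant: VariantRecord
    stage_results: dict = field(default_factory=dict)  # stage -> 'pass'/'fail'/'NA'
    final_status: str = "rejected"  # 'nominated' | 'rescued' | 'rejected(<stage>)'
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.final_status in ("nominated", "rescued")

    def failed_stage(self) -> Optional[str]:
        for stage, res in self.stage_results.items():
            if res == "fail":
                return stage
        return None


def evidence_filter(v: VariantRecord, cfg: FilterConfig) -> tuple[bool, str]:
    """Depth/VAF evidence band: depth >= min_depth and vaf_low <= VAF <= vaf_high.

    Both band endpoints are inclusive. Returns (passed, reason).
    """
    if v.total_depth is None or v.vaf is None:
        return False, "no-evidence"
    if v.total_depth < cfg.min_depth:
        return False, f"depth {v.total_depth} < {cfg.min_depth}"
    if v.vaf < cfg.vaf_low:
        return False, f"vaf {v.vaf:.3f} below band"
    if v.vaf > cfg.vaf_high:
        return False, f"vaf {v.vaf:.3f} above band"
    return True, ""


def run_cascade(
    variants: Iterable[VariantRecord],
    cfg: FilterConfig,
    consequence_fn: Callable,
    hotspot_fn: Callable,
) -> list[FilterTrace]:
    """Apply the five-stage cascade to every variant.

    ``consequence_fn(variant)`` returns a ConsequenceCall (filling the gene
    annotation used by the gene_list stage); ``hotspot_fn(call)`` returns a
    matching hotspot entry or None. A variant failing stage k records NA for
    all later stages. With ``hotspot_only=False`` the hotspot stage is
    skipped (recorded NA), yielding a survivor superset.
    """
    from ameloseq.consequence import is_high_consequence

    traces = []
    for v in variants:
        call = consequence_fn(v)
        trace = FilterTrace(variant=v, stage_results={s: "NA" for s in STAGES})

        def run(stage: str, passed: bool, reason: str = "") -> bool:
            trace.stage_results[stage] = "pass" if passed else "fail"
            if not passed:
                trace.final_status = f"rejected({stage})"
                trace.reason = reason or stage
            return passed

        gene = (call.gene_symbol or "").upper()
        ok = run("gene_list", bool(gene) and gene in cfg.gene_list, f"gene {gene or '?'} not in list")
        if ok:
            ok = run("known_snp", v.site_allele not in cfg.known_snp_sites, "known germline SNP")
        if ok:
            passed, reason = evidence_filter(v, cfg)
            ok = run("evidence", passed, reason)
        if ok:
            ok = run("consequence", is_high_consequence(call), f"class {call.klass}")
        if ok and cfg.hotspot_only:
            ok = run("hotspot", hotspot_fn(call) is not None, "no hotspot orthology")
        if ok:
            trace.final_status = "nominated"
        v.annotations["filter_status"] = trace.final_status
        traces.append(trace)
    return traces


def rescue_at_hotspots(
    traces: Sequence[FilterTrace],
    cfg: FilterConfig,
    hotspot_loci: set,
) -> list[FilterTrace]:
    """Targeted low-VAF rescue at mapped hotspot loci.

    ``hotspot_loci`` is the set of genomic (chrom, pos) positions of mapped
    canine hotspot codons — the loci one would manually inspect. A trace is
    promoted to ``rescued`` iff:

    * it was rejected at the evidence stage with all earlier stages passing
      (i.e. it failed ONLY the evidence test);
    * its locus is in ``hotspot_loci``;
    * rescue_vaf_floor <= VAF <= vaf_high and alt_depth >= rescue_min_alt_reads.

    All other traces are returned unchanged; statuses only ever move
    rejected -> rescued.
    """
    out = []
    for t in traces:
        promote = (
            t.final_status == "rejected(evidence)"
            and t.stage_results.get("gene_list") == "pass"
            and t.stage_results.get("known_snp") == "pass"
            and t.variant.site in hotspot_loci
            and t.variant.vaf is not None
            and cfg.rescue_vaf_floor <= t.variant.vaf <= cfg.vaf_high
            and (t.variant.alt_depth or 0) >= cfg.rescue_min_alt_reads
        )
        if promote:
            t = replace(
                t,
                stage_results=dict(t.stage_results),
                final_status="rescued",
                reason="low-VAF hotspot rescue",
            )
            t.variant.annotations["filter_status"] = "rescued"
        out.append(t)
    return out


def write_trace_report(traces: Sequence[FilterTrace], path) -> None:
    """TSV trace report: one row per variant with per-stage results."""
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tchrom\tpos\tref\talt\tdepth\tvaf\tgene\tconsequence\t"
            + "\t".join(STAGES)
            + "\tfinal_status\treason\n"
        )
        for t in traces:
            v = t.variant
            vaf = f"{v.vaf:.4f}" if v.vaf is not None else ""
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.total_depth if v.total_depth is not None else ''}\t{vaf}\t"
                f"{v.annotations.get('gene', '')}\t{v.annotations.get('consequence', '')}\t"
                + "\t".join(t.stage_results[s] for s in STAGES)
                + f"\t{t.final_status}\t{t.reason}\n"
            )
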